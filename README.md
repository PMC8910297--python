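# titrakit

Quantitative binding analysis for protein–ligand titrations followed by
solution methods: NMR chemical-shift-perturbation (CSP) mapping with Kd
fitting, fluorescence-anisotropy (FA) titration analysis, and
residence-time/dihedral post-processing of binding–unbinding trajectories.
The package targets the weak-to-medium affinity regime (Kd roughly 1 μM –
10 mM) typical of protein–carbohydrate interactions, e.g. human galectin-3
CRD binding digalactoside ligands, and ships seeded synthetic-data
generators so every analysis stage can be validated against planted ground
truth.

## The model

For a 1:1 complex P + L ⇌ PL under fast exchange, each amide cross peak in
a ¹⁵N-¹H HSQC titration moves with the bound-state population. Peak
displacement is summarized by the combined shift distance

```
d = sqrt( (ΔδH² + (α·ΔδN)²) / 2 ),        α = 0.14
```

and the observed shift change at total concentrations [P]t, [L]t follows
the exact ligand-depletion isotherm (no excess-ligand approximation):

```
Δd = Δd_max · { ([P]t+[L]t+Kd) − sqrt( ([P]t+[L]t+Kd)² − 4[P]t[L]t ) } / 2[P]t
```

Kd is estimated by nonlinear least squares, per residue or globally over a
residue set with one shared Kd and one Δd_max per residue. FA titrations
are fitted with the one-site model r(L) = r_free + (r_bound − r_free)·fB
(with optional depletion), after inner-filter and dilution corrections; a
linear-vs-saturating F-test decides whether a response shows specific
binding at all. Distance traces are segmented into bound-state intervals by
hysteresis thresholding, giving residence-time statistics; signed dihedrals
and circular means cover torsion analysis.

## Worked example

Simulate a galectin-like titration (143 residues, planted Kd = 123 μM,
[P]t = 270 μM, 12 points), classify the perturbed residues, and fit a
shared Kd over the top-ranked nine:

```
$ titrakit simulate --kd 123 --seed 11 -o titration.csv
$ titrakit csp titration.csv | head -5
residue_id  residue_name  d_final_ppm  class   rank
158         HIS           0.13189      strong  1
174         ASN           0.11482      strong  2
175         THR           0.07153      strong  3
176         LYS           0.06591      strong  4

$ titrakit fit titration.csv
{
  "mode": "global",
  "residues": [158, 174, 175, 176, 182, 184, 190, 183, 188],
  "Kd_uM": 132.70601283208873,
  "Kd_se_uM": 6.025318754929927,
  ...
}
```

The classification ranks the planted binding-site residues (His158, Asn174,
Thr175, Lys176 and the 182–190 stretch) at the top, and the shared-Kd fit
returns 132.7 ± 6.0 μM for this noisy realization — within two standard
errors of the planted 123 μM. `titrakit fa-fit`, `titrakit traj` and
`titrakit report` (config-driven end-to-end run) follow the same pattern;
see `--help` on each subcommand.

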