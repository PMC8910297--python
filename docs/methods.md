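# Methods

## Scope and assumptions

titrakit analyzes 1:1 protein–ligand binding equilibria observed through
three channels: HSQC chemical-shift-perturbation titrations, intrinsic
tryptophan fluorescence anisotropy, and reduced observables of
binding/unbinding trajectories (protein–ligand distance traces, torsion
angles). The central assumptions are:

* **Single site, 1:1 stoichiometry.** All binding models derive from
  P + L ⇌ PL mass balance. Multi-site, cooperative, or competitive schemes
  are out of scope.
* **Fast exchange.** Observed chemical shifts are population-weighted
  averages of the free and bound states, appropriate for the μM–mM
  affinity regime without appreciable exchange broadening. No lineshape or
  exchange-regime analysis is attempted.
* **Exact ligand depletion.** The bound fraction is always computed from
  the quadratic mass-balance solution, so protein concentrations
  comparable to Kd (the normal situation in protein-observed NMR, where
  sensitivity dictates 100+ μM protein) are handled without the
  excess-ligand approximation. The rationalized root
  fB = 2[L]t / (S + sqrt(S² − 4[P]t[L]t)), S = [P]t+[L]t+Kd, is used
  throughout; it is algebraically identical to the textbook form but
  avoids catastrophic cancellation when Kd ≪ [P]t, [L]t.

## CSP mapping

Peak displacements are collapsed to the combined shift distance
d = sqrt((ΔδH² + (α·ΔδN)²)/2) with a single global α = 0.14, the
conventional down-weighting of the ¹⁵N axis; no residue-type-specific α
(e.g. glycine) is applied. Per-residue Δd profiles are measured against
the apo reference point; residues whose reference peak is overlapped or
missing are dropped entirely (no baseline), and unusable later points
appear as explicit NaN gaps — never imputed, since an overlapped peak
carries no positional evidence.

Classification uses the final titration point (largest bound population,
best contrast) and a μ + kσ ladder over the final-Δd distribution of all
fully observed residues: strong above μ+2σ, intermediate above μ+σ, minor
above μ, else unperturbed. The ladder is affine in the data, so the
classification is invariant under a common rescaling of all Δd; a
`fixed_cutoffs` method accepts absolute ppm thresholds instead. Residues
with any unusable point are reported as `excluded` and ranked after all
others. The strict threshold comparisons carry a ~1e-9 relative guard so
that an exactly degenerate input (all residues equal) classifies as
unperturbed instead of flipping on the float rounding of the mean.

## Kd fitting

Individual fits estimate (Kd, Δd_max) per residue; global fits share one
Kd across a residue set with one Δd_max per residue (different residues
have different bound-state shifts, so a shared amplitude would be
unphysical). Observations are uniformly weighted. Optimization is
Levenberg–Marquardt least squares (lmfit/MINPACK) with xtol = ftol =
1e-10 and a generous evaluation budget; initialization is scale-free:
Kd₀ = median nonzero [L]t, Δd_max,₀ = 1.2 × the last observed Δd.
Non-convergence is reported in the result object, not raised.

Standard errors come from the residual-variance-scaled Gauss–Newton
covariance by default; a residual-resampling bootstrap (seeded, fully
deterministic) is available as a cross-check and agrees with the
covariance SE within ~30% on well-conditioned synthetic data. A singular
information matrix yields an infinite SE plus a warning flag rather than
an exception.

CSP-based Kd determination is reliable roughly within 1 μM < Kd < 10 mM.
Results carry an applicability flag that trips at twofold inside each
endpoint (below 2 μM: the titration turns stoichiometric and the curve
shape loses Kd information; above 5 mM: the isotherm is nearly linear over
any achievable ligand range). A practical consequence, reproduced by the
test suite: with a ligand series designed for a ~100 μM interaction (fixed
by ligand solubility), planting the true Kd in the multi-mM regime
inflates the relative SE several-fold — weak binders are measurable but
poorly determined.

## Fluorescence anisotropy

Readings are corrected for the inner-filter effect with the half-path
approximation F_corr = F_obs·10^((A_ex+A_em)/2) (isolated in one function
so an instrument-specific variant can be substituted) and for titrant
dilution by (V₀+V_added)/V₀. The one-site model is fitted with either the
excess-ligand hyperbola or the depletion quadratic; the two agree as
[P]t/Kd → 0 (verified at 10⁻³ to <0.5% in Kd).

"No specific binding" is operationalized as a model comparison: a straight
line (2 parameters) against the one-site saturating curve (3 parameters),
compared by an F-test with one extra parameter at level 0.05. The verdict
is additionally negative when the fitted Kd exceeds the largest ligand
concentration tested — a half-saturation point outside the probed range is
not evidence of binding. Measured on 500 linear-null simulations, the
empirical false-positive rate is ~3–5%, within the nominal level.

## Trajectory post-processing

Distance traces are segmented with hysteresis: the bound state is entered
below `threshold_low` and left only above `threshold_high` (defaults 5 and
10 Å; both always explicit in the CLI), so level noise smaller than the
dead band cannot fragment a dwell. After thresholding, unbound gaps
shorter than `min_dwell` are closed and remaining sub-`min_dwell` bound
segments dropped. Residence statistics optionally censor a final segment
that abuts the trace end (an interrupted dwell, not a dissociation);
whether to censor is a user decision because simulations are routinely
terminated mid-dwell.

Dihedrals use the IUPAC sign convention (cis = 0°, positive clockwise
looking along the central bond) via the atan2 formulation, which is
numerically stable near ±180°; collinear point triples are rejected.
Torsion populations near ±180° or split across the wrap are summarized
with the circular mean (atan2 of mean sine/cosine), undefined by design
when the resultant length is ~0.

## Synthetic data: what it emulates, and what not

The generators produce data with exactly the statistical structure the
analyses assume: population-weighted fast-exchange peak movement with
i.i.d. Gaussian position noise per axis (defaults σH = 0.002 ppm,
σN = 0.02 ppm, of the order of the digital resolution of a typical 2D
HSQC), one-site FA curves or a linear nonspecific null, and two-state
telegraph distance traces with exponential dwells starting bound
(complexed start). Defaults mirror the motivating study conditions:
[P]t = 270 μM for NMR titrations, a 12-point geometric ligand ladder from
Kd/4 to 10×Kd, FA at [P]t = 3 μM with r_free = 0.10, r_bound = 0.20, and
residence-time scenarios around mean bound dwells of hundreds of ns. The
demo residue panel (numbering 108–250) plants the canonical S-face
perturbation pattern of a galactoside binder: large shifts at His158 and
Asn174, intermediate at Thr175/Lys176, small at Phe159/Asn160, a moderate
182–190 stretch, and a remote reporter at Asn222.

Passing recovery tests on these data shows the estimators are correct and
well calibrated *under the model*. Real spectra additionally contain peak
overlap, titration-dependent linewidths, assignment errors, correlated
baseplane noise, and slow-exchange contributions — none of which are
emulated, so recovery rates here are an upper bound on real-data
performance.

Every generator is a pure function of (design, seed); the pipeline driver
derives per-stage seeds from one root seed by stable hashing (CRC32,
masked below 2³¹).

## Problem sizes in tests and the acceptance script

Stochastic checks use 20 seeded replicates per scenario and report
medians; the calibration study uses 100 datasets with Kd log-uniform in
[10 μM, 1 mM]; the null-calibration of the specificity test uses 500
simulations; residence-time recovery uses traces with ~500 bound events
(sampling error of an exponential mean at n≈500 is ~4.5%). These sizes
make every Monte-Carlo band comfortably tighter than the acceptance
tolerance it feeds while keeping the whole suite in tens of seconds.

## Known limitations

* No multi-site/cooperative models; no slow- or intermediate-exchange
  treatment; no lineshape analysis.
* No NMR-STAR/Sparky peak-list ingestion (long/wide CSV dialects only);
  no trajectory-file parsing (distance traces are plain CSV).
* Anisotropy is taken as provided; no G-factor computation from raw
  polarized intensities, no wavelength-resolved (red-shift) analysis.
* The PDB writer edits only the B-factor column of `ATOM`/`HETATM`
  records and leaves every other byte untouched; it does not validate
  full PDB semantics.
* Dihedral sign conventions in the literature differ by mirror symmetry;
  the convention here is fixed and documented rather than auto-detected.
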