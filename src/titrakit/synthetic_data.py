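"""Seeded synthetic-data generators with the statistical structure the
analyses assume.

Three generators cover the three measurement channels:

* :func:`simulate_titration` — fast-exchange HSQC titrations: each residue's
  observed peak is the population-weighted average of its free and bound
  positions, with the bound population given by the exact 1:1 depletion
  isotherm and independent Gaussian position noise per axis (defaults
  σH = 0.002 ppm, σN = 0.02 ppm, of the order of the digital resolution of a
  typical 500 MHz HSQC).
* :func:`simulate_fa_titration` — one-site anisotropy saturation curves
  (with ligand depletion), or, with ``true_Kd = inf``, the nonspecific null:
  flat anisotropy and a linearly decreasing intensity.
* :func:`simulate_distance_trace` — two-state telegraph distance traces with
  exponential dwell times, starting in the bound state (complexed start),
  for residence-time analysis.

Every generator is a pure function of its design and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from titrakit.binding_fit import fraction_bound
from titrakit.fluorescence import AnisotropySeries
from titrakit.peak_io import PeakPosition, Quality, TitrationDataset, TitrationPoint
from titrakit.traj_geometry import DistanceTrace

__all__ = [
    "ResidueSpec",
    "TitrationDesign",
    "TelegraphDesign",
    "simulate_titration",
    "design_ligand_series",
    "simulate_fa_titration",
    "simulate_distance_trace",
    "galectin_demo_residues",
]

DEFAULT_NOISE_H = 0.002  # ppm
DEFAULT_NOISE_N = 0.02  # ppm


@dataclass(frozen=True)
class ResidueSpec:
    """Free-state peak position and bound-state offset of one residue."""

    residue_id: int
    free_H: float  # ppm
    free_N: float  # ppm
    offset_H: float  # ΔδH on full saturation, ppm
    offset_N: float  # ΔδN on full saturation, ppm
    residue_name: str = "UNK"


@dataclass
class TitrationDesign:
    """Ground truth for one synthetic HSQC titration."""

    protein_total: float  # μM
    ligand_points: list[float]  # μM, first must be 0
    residues: list[ResidueSpec]
    true_Kd: float  # μM
    noise_H: float = DEFAULT_NOISE_H
    noise_N: float = DEFAULT_NOISE_N
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ligand_points or self.ligand_points[0] != 0:
            raise ValueError("ligand_points must start at 0 (apo reference)")
        if self.noise_H < 0 or self.noise_N < 0:
            raise ValueError("noise must be >= 0")
        if self.true_Kd <= 0:
            raise ValueError("true_Kd must be > 0")


def simulate_titration(design: TitrationDesign) -> TitrationDataset:
    """Generate a fast-exchange titration dataset from planted parameters.

    At each point the bound fraction fB follows the depletion isotherm and
    each residue's peak sits at free + fB·offset plus axis-wise Gaussian
    noise.  The apo reference is noisy too (offsets are measured against
    noiseless truth only at fB = 0 in expectation).
    """
    rng = np.random.default_rng(design.seed)
    points: list[TitrationPoint] = []
    for i, lt in enumerate(design.ligand_points):
        fb = fraction_bound(design.protein_total, lt, design.true_Kd) if lt > 0 else 0.0
        peaks: dict[int, PeakPosition] = {}
        for r in design.residues:
            dh = r.free_H + fb * r.offset_H + rng.normal(0.0, design.noise_H)
            dn = r.free_N + fb * r.offset_N + rng.normal(0.0, design.noise_N)
            peaks[r.residue_id] = PeakPosition(
                r.residue_id, r.residue_name, dh, dn, Quality.OK
            )
        points.append(TitrationPoint(i, design.protein_total, lt, peaks))
    return TitrationDataset(
        points=points,
        metadata={"generator": "simulate_titration", "seed": str(design.seed)},
    )


def design_ligand_series(
    Pt: float, Kd_guess: float, n_points: int, max_fold_Kd: float = 10.0
) -> list[float]:
    """Ligand-concentration ladder for a titration: 0 plus a geometric grid
    from Kd/4 to ``max_fold_Kd``·Kd, which brackets the curved region of the
    isotherm for the guessed affinity."""
    if n_points < 4:
        raise ValueError("need n_points >= 4")
    if Kd_guess <= 0 or max_fold_Kd <= 0.25:
        raise ValueError("Kd_guess must be > 0 and max_fold_Kd > 1/4")
    grid = np.geomspace(Kd_guess / 4.0, max_fold_Kd * Kd_guess, n_points - 1)
    return [0.0] + [float(x) for x in grid]


def simulate_fa_titration(
    protein_total: float,
    true_Kd: float,
    r_free: float,
    r_bound: float,
    ligand_points,
    noise_r: float = 0.002,
    intensity_slope: float = 0.0,
    intensity_0: float = 100.0,
    seed: int = 0,
) -> AnisotropySeries:
    """Generate a fluorescence-anisotropy titration.

    Specific mode (finite ``true_Kd``): anisotropy follows the one-site
    curve with depletion.  Nonspecific mode (``true_Kd = math.inf``): the
    anisotropy is flat at ``r_free`` plus noise — no complex forms — while
    the intensity decreases linearly with ligand at ``intensity_slope``
    (a.u. per μM), emulating dilution/quenching without specific binding.
    """
    rng = np.random.default_rng(seed)
    L = np.asarray(ligand_points, dtype=float)
    if math.isinf(true_Kd):
        r = np.full(L.size, r_free)
    else:
        fb = fraction_bound(protein_total, L, true_Kd)
        r = r_free + (r_bound - r_free) * fb
    r = r + rng.normal(0.0, noise_r, size=L.size)
    intensity = intensity_0 * (1.0 + intensity_slope * L)
    return AnisotropySeries(
        ligand_total=L,
        anisotropy=np.clip(r, -0.2, 0.4),
        protein_total=protein_total,
        intensity=intensity,
    )


@dataclass
class TelegraphDesign:
    """Two-state bound/unbound telegraph process with exponential dwells."""

    mean_bound_dwell: float  # ns
    mean_unbound_dwell: float  # ns
    bound_level: float  # Å
    unbound_level: float  # Å
    level_noise: float  # Å s.d.
    dt: float  # ns
    duration: float  # ns
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_bound_dwell <= 0 or self.mean_unbound_dwell <= 0:
            raise ValueError("dwell means must be > 0")
        if self.bound_level >= self.unbound_level:
            raise ValueError("bound_level must be < unbound_level")
        if self.dt >= min(self.mean_bound_dwell, self.mean_unbound_dwell) / 10.0:
            raise ValueError("dt must be < min dwell mean / 10")


def simulate_distance_trace(design: TelegraphDesign) -> DistanceTrace:
    """Generate a two-state distance trace, starting bound.

    Dwell times alternate bound/unbound with exponential distributions; the
    distance is the state level plus i.i.d. Gaussian noise per sample.  A
    duration shorter than 5 expected bound/unbound cycles sets a
    ``short_trace`` warning in the metadata.
    """
    rng = np.random.default_rng(design.seed)
    cycle = design.mean_bound_dwell + design.mean_unbound_dwell
    n_samples = int(round(design.duration / design.dt))
    # alternating exponential dwells until the trace is covered
    dwells: list[float] = []
    covered, bound_state = 0.0, True
    while covered < design.duration:
        mean = design.mean_bound_dwell if bound_state else design.mean_unbound_dwell
        w = float(rng.exponential(mean))
        dwells.append(w)
        covered += w
        bound_state = not bound_state
    boundaries = np.cumsum(dwells)
    t = (np.arange(n_samples) + 0.5) * design.dt
    state_idx = np.searchsorted(boundaries, t, side="right")
    bound = state_idx % 2 == 0  # dwell 0 is bound, strict alternation
    level = np.where(bound, design.bound_level, design.unbound_level)
    noise = (
        rng.normal(0.0, design.level_noise, size=n_samples)
        if design.level_noise > 0
        else 0.0
    )
    meta: dict = {"seed": design.seed, "n_dwells": len(dwells)}
    if design.duration < 5.0 * cycle:
        meta["warning"] = "short_trace: fewer than 5 expected cycles"
    return DistanceTrace(
        t=np.arange(n_samples) * design.dt,
        distance=level + noise,
        dt=design.dt,
        metadata=meta,
    )


def galectin_demo_residues(seed: int = 97) -> list[ResidueSpec]:
    """A galectin-CRD-like residue panel (numbering 108–250, 143 residues).

    Bound-state offsets plant the canonical perturbation pattern of a
    β-galactoside binding to the S-face site: large shifts at His158 and
    Asn174, intermediate at Thr175/Lys176, small at Phe159/Asn160, a
    moderately shifted 182–190 stretch covering the distal subsite, and a
    remote reporter at Asn222; all other residues carry no bound-state
    shift.  Free-state positions are drawn once from the typical amide
    region (seeded, so the panel is reproducible).
    """
    rng = np.random.default_rng(seed)
    offsets: dict[int, tuple[float, float, str]] = {
        158: (0.16, 0.9, "HIS"),
        174: (0.15, 0.8, "ASN"),
        175: (0.09, 0.55, "THR"),
        176: (0.08, 0.50, "LYS"),
        159: (0.025, 0.15, "PHE"),
        160: (0.022, 0.12, "ASN"),
        222: (0.06, 0.40, "ASN"),
    }
    for rid in range(182, 191):
        offsets[rid] = (0.07, 0.45, "UNK")
    residues = []
    for rid in range(108, 251):
        free_h = float(rng.uniform(7.0, 9.5))
        free_n = float(rng.uniform(105.0, 130.0))
        dh, dn, name = offsets.get(rid, (0.0, 0.0, "UNK"))
        residues.append(ResidueSpec(rid, free_h, free_n, dh, dn, name))
    return residues
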