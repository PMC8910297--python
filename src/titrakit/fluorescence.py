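"""Fluorescence-anisotropy titration analysis.

Intrinsic tryptophan fluorescence (excitation near 295 nm) reports on
ligand binding when a Trp side chain stacks against the ligand — for
galectins, W181 against the galactose ring.  The anisotropy r of the
titrated sample follows the one-site binding curve

    r([L]) = r_free + (r_bound − r_free) · fB

where fB is the bound fraction, either the excess-ligand hyperbola
L/(Kd + L) or the exact depletion quadratic when the protein concentration
is not negligible against Kd.

Two measurement corrections are provided: the inner-filter correction
F_corr = F_obs · 10^((A_ex + A_em)/2) for attenuation by sample absorbance
(half-path approximation), and a dilution correction for titrant volume.

A specificity test formalizes the judgement that a response "follows a
straight line": the saturating one-site model must beat a straight line by
an F-test, and its fitted Kd must lie inside the titrated range, otherwise
no specific binding is declared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np
from scipy import stats

from titrakit.binding_fit import fraction_bound

__all__ = [
    "AnisotropySeries",
    "FASpecificityVerdict",
    "OneSiteFAFit",
    "inner_filter_correct",
    "dilution_correct",
    "fit_one_site",
    "test_specific_binding",
]

_ANISO_RANGE = (-0.2, 0.4)


@dataclass
class AnisotropySeries:
    """One FA titration: ligand concentrations with readings per point."""

    ligand_total: np.ndarray  # μM
    anisotropy: np.ndarray  # dimensionless r
    protein_total: float  # μM
    intensity: np.ndarray | None = None  # corrected fluorescence, a.u.
    absorbance_ex: np.ndarray | None = None
    absorbance_em: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ligand_total = np.asarray(self.ligand_total, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if self.ligand_total.shape != self.anisotropy.shape:
            raise ValueError("ligand_total and anisotropy must have equal length")
        if np.any(np.diff(self.ligand_total) < 0):
            raise ValueError("ligand_total must be nondecreasing")
        lo, hi = _ANISO_RANGE
        if np.any((self.anisotropy < lo) | (self.anisotropy > hi)):
            raise ValueError(f"anisotropy outside physical range [{lo}, {hi}]")
        if self.protein_total <= 0:
            raise ValueError("protein_total must be > 0")


def inner_filter_correct(F_obs, A_ex, A_em):
    """Correct fluorescence for primary+secondary inner-filter attenuation.

    Half-path approximation: the excitation beam is attenuated over half the
    cell before the observation volume and the emission over half on the way
    out, so F_corr = F_obs · 10^((A_ex + A_em)/2).
    """
    A_ex = np.asarray(A_ex, dtype=float)
    A_em = np.asarray(A_em, dtype=float)
    if np.any(A_ex < 0) or np.any(A_em < 0):
        raise ValueError("absorbances must be >= 0")
    out = np.asarray(F_obs, dtype=float) * 10.0 ** ((A_ex + A_em) / 2.0)
    return float(out) if out.ndim == 0 else out


def dilution_correct(values, volumes_added, initial_volume: float):
    """Scale readings back to the initial volume after titrant additions.

    ``volumes_added`` is the cumulative added volume per point (same unit as
    ``initial_volume``); each value is multiplied by
    (V₀ + V_added) / V₀.
    """
    v = np.asarray(volumes_added, dtype=float)
    if initial_volume <= 0:
        raise ValueError("initial_volume must be > 0")
    if np.any(v < 0) or np.any(np.diff(np.atleast_1d(v)) < 0):
        raise ValueError("volumes_added must be nonnegative and cumulative")
    out = np.asarray(values, dtype=float) * (initial_volume + v) / initial_volume
    return float(out) if out.ndim == 0 else out


@dataclass
class OneSiteFAFit:
    Kd: float  # μM
    r_free: float
    r_bound: float
    Kd_se: float
    rss: float
    converged: bool
    saturation_reached: float  # fraction of fitted span covered by the data
    warning: str | None = None


def _one_site_r(L, Pt, Kd, r_free, r_bound, deplete: bool):
    if deplete:
        fB = fraction_bound(Pt, L, Kd)
    else:
        fB = L / (Kd + L)
    return r_free + (r_bound - r_free) * fB


def fit_one_site(series: AnisotropySeries, deplete: bool = False) -> OneSiteFAFit:
    """Fit the one-site specific-binding model to an anisotropy titration.

    With ``deplete=True`` the bound fraction comes from the exact 1:1
    depletion quadratic (protein as the observed species, ligand as
    titrant); with ``deplete=False`` the excess-ligand hyperbola is used.
    The two agree as protein_total/Kd → 0.

    Requires ≥ 5 points spanning two decades in ligand concentration or
    reaching ≥ 70% of the fitted saturation; if the observed span covers
    less than 30% of the fitted (r_bound − r_free) the estimates are
    returned with a warning.
    """
    L = series.ligand_total
    r = series.anisotropy
    if L.size < 5:
        raise ValueError(f"need >= 5 titration points, got {L.size}")
    nz = L[L > 0]
    span_decades = math.log10(nz.max() / nz.min()) if nz.size >= 2 else 0.0

    params = lmfit.Parameters()
    params.add("Kd", value=float(np.median(nz)), min=1e-9)
    params.add("r_free", value=float(r[0]), min=-0.2, max=0.4)
    params.add("r_bound", value=float(r[-1]), min=-0.2, max=0.4)

    def residual(p):
        return r - _one_site_r(
            L, series.protein_total, p["Kd"].value, p["r_free"].value,
            p["r_bound"].value, deplete,
        )

    res = lmfit.minimize(residual, params, method="leastsq", xtol=1e-10, ftol=1e-10)
    kd = float(res.params["Kd"].value)
    r_free = float(res.params["r_free"].value)
    r_bound = float(res.params["r_bound"].value)
    span = r_bound - r_free
    covered = float((r[-1] - r[0]) / span) if span != 0 else 0.0
    warning = None
    if covered < 0.30:
        warning = "saturation not approached: data cover <30% of fitted span"
    elif covered < 0.70 and span_decades < 2.0:
        warning = "series neither spans 2 decades nor reaches 70% saturation"
    kd_se = res.params["Kd"].stderr
    return OneSiteFAFit(
        Kd=kd,
        r_free=r_free,
        r_bound=r_bound,
        Kd_se=float(kd_se) if kd_se is not None else float("inf"),
        rss=float(np.sum(np.asarray(res.residual) ** 2)),
        converged=bool(res.success),
        saturation_reached=covered,
        warning=warning,
    )


@dataclass(frozen=True)
class FASpecificityVerdict:
    """Outcome of the linear-vs-saturating model comparison."""

    specific: bool
    linear_rss: float
    saturating_rss: float
    f_statistic: float
    p_value: float
    criterion: str


def test_specific_binding(
    series: AnisotropySeries, alpha: float = 0.05, response: str = "anisotropy"
) -> FASpecificityVerdict:
    """Decide whether a titration response shows specific (saturating) binding.

    Fits a straight line (2 parameters) and the one-site saturating model
    (3 parameters) to the response and compares residual sums of squares by
    an F-test with one extra parameter.  ``specific=False`` when the
    saturating model does not significantly reduce the RSS at level
    ``alpha``, or when the fitted Kd exceeds the largest ligand
    concentration tested (a half-saturation point outside the probed range
    is not evidence of binding).  A flat response short-circuits to
    ``specific=False``.
    """
    L = series.ligand_total
    if L.size < 6:
        raise ValueError(f"need >= 6 points, got {L.size}")
    if response == "anisotropy":
        y = series.anisotropy
    elif response == "intensity":
        if series.intensity is None:
            raise ValueError("series carries no intensity readings")
        y = np.asarray(series.intensity, dtype=float)
    else:
        raise ValueError(f"unknown response {response!r}")

    if np.ptp(y) == 0:
        return FASpecificityVerdict(
            specific=False, linear_rss=0.0, saturating_rss=0.0,
            f_statistic=0.0, p_value=1.0, criterion="flat response",
        )

    # straight line, 2 params
    coef = np.polyfit(L, y, 1)
    rss_lin = float(np.sum((y - np.polyval(coef, L)) ** 2))

    # one-site saturating model, 3 params (amplitude may have either sign)
    params = lmfit.Parameters()
    nz = L[L > 0]
    params.add("Kd", value=float(np.median(nz)), min=1e-9)
    params.add("y0", value=float(y[0]))
    params.add("amp", value=float(y[-1] - y[0]))

    def residual(p):
        fB = fraction_bound(series.protein_total, L, p["Kd"].value)
        return y - (p["y0"].value + p["amp"].value * fB)

    res = lmfit.minimize(residual, params, method="leastsq", xtol=1e-10, ftol=1e-10)
    rss_sat = float(np.sum(np.asarray(res.residual) ** 2))
    kd = float(res.params["Kd"].value)

    df_sat = L.size - 3
    if rss_sat <= 0 or df_sat <= 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (rss_lin - rss_sat) / 1.0 / (rss_sat / df_sat)
        f_stat = max(f_stat, 0.0)
        p = float(stats.f.sf(f_stat, 1, df_sat))

    if p >= alpha:
        return FASpecificityVerdict(
            False, rss_lin, rss_sat, f_stat, p,
            f"saturating model not better than line (F-test p={p:.3g})",
        )
    if kd > float(L.max()):
        return FASpecificityVerdict(
            False, rss_lin, rss_sat, f_stat, p,
            f"fitted Kd {kd:.3g} μM beyond max tested ligand {L.max():.3g} μM",
        )
    return FASpecificityVerdict(
        True, rss_lin, rss_sat, f_stat, p,
        f"saturating model preferred (F-test p={p:.3g}), Kd in tested range",
    )
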