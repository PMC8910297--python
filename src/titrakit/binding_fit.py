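"""Dissociation-constant fitting from CSP titration profiles.

For a 1:1 complex P + L ⇌ PL with total concentrations [P]t and [L]t, mass
balance gives the bound-protein fraction exactly (no excess-ligand
approximation), so titrations where ligand is depleted by binding are
handled correctly:

    fB = { ([P]t+[L]t+Kd) − sqrt( ([P]t+[L]t+Kd)² − 4[P]t[L]t ) } / 2[P]t

Under fast exchange the observed combined shift change is Δd = Δd_max · fB,
with Δd_max the (fitted) saturation amplitude of that residue.  Fits are
nonlinear least squares, either per residue (Kd, Δd_max) or global over a
residue set with one shared Kd and one Δd_max per residue.

CSP-based Kd determination is reliable roughly for 1 μM < Kd < 10 mM; the
result carries an applicability flag that trips at twofold inside each
endpoint, since estimates near the weak limit carry large uncertainty (the
curve becomes nearly linear in [L]t) and near the tight limit the titration
turns stoichiometric and shape information about Kd vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import lmfit
import numpy as np

from titrakit.csp_mapping import CSPProfile
from titrakit.peak_io import TitrationDataset

__all__ = [
    "Applicability",
    "BindingFitResult",
    "binding_isotherm",
    "fraction_bound",
    "fit_individual",
    "fit_global",
    "estimate_uncertainty",
    "KD_WINDOW_UM",
]

#: stated applicability window of CSP-based Kd fitting, μM
KD_WINDOW_UM = (1.0, 10_000.0)
#: soft flags trip at 2x inside each endpoint
_TIGHT_FLAG_UM = 2.0 * KD_WINDOW_UM[0]
_WEAK_FLAG_UM = KD_WINDOW_UM[1] / 2.0

_XTOL = 1e-10
_MAX_ITER = 500


def fraction_bound(Pt, Lt, Kd):
    """Exact bound-protein fraction of the 1:1 depletion isotherm.

    All concentrations in the same unit (μM conventionally); depends only on
    the ratios Lt/Pt and Kd/Pt.  Uses the rationalized root
    2·Lt / (S + sqrt(S² − 4·Pt·Lt)), S = Pt+Lt+Kd, which avoids the
    catastrophic cancellation of the textbook form when Kd ≪ Pt, Lt.
    """
    Pt = np.asarray(Pt, dtype=float)
    Lt = np.asarray(Lt, dtype=float)
    if np.any(Pt <= 0):
        raise ValueError("protein concentration must be > 0")
    if np.any(Lt < 0):
        raise ValueError("ligand concentration must be >= 0")
    if np.any(np.asarray(Kd) <= 0):
        raise ValueError("Kd must be > 0")
    S = Pt + Lt + Kd
    disc = S * S - 4.0 * Pt * Lt
    f = 2.0 * Lt / (S + np.sqrt(np.maximum(disc, 0.0)))
    out = np.asarray(f, dtype=float)
    return float(out) if out.ndim == 0 else out


def binding_isotherm(Pt, Lt, Kd, dmax):
    """Observed shift change Δd (ppm) for saturation amplitude ``dmax``."""
    if np.any(np.asarray(dmax) < 0):
        raise ValueError("dmax must be >= 0")
    f = fraction_bound(Pt, Lt, Kd)
    return dmax * f


class Applicability:
    OK = "ok"
    NEAR_WEAK_LIMIT = "near_weak_limit"
    NEAR_TIGHT_LIMIT = "near_tight_limit"


def _applicability(kd_um: float) -> str:
    if kd_um > _WEAK_FLAG_UM:
        return Applicability.NEAR_WEAK_LIMIT
    if kd_um < _TIGHT_FLAG_UM:
        return Applicability.NEAR_TIGHT_LIMIT
    return Applicability.OK


@dataclass
class BindingFitResult:
    """Result of an isotherm fit (individual or global).

    ``Kd_se`` is the covariance-based standard error by default;
    :func:`estimate_uncertainty` can replace it with a bootstrap SE.
    """

    Kd_hat: float  # μM
    Kd_se: float  # μM
    dmax_hat: dict[int, float]  # residue_id -> ppm
    dmax_se: dict[int, float]
    residuals: np.ndarray
    rss: float
    converged: bool
    n_obs: int
    applicability: str
    se_method: str = "covariance"
    se_warning: str | None = None

    def report(self) -> dict:
        """JSON-serializable summary."""
        return {
            "Kd_uM": self.Kd_hat,
            "Kd_se_uM": self.Kd_se,
            "dmax_ppm": {str(k): v for k, v in self.dmax_hat.items()},
            "rss": self.rss,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "applicability": self.applicability,
            "se_method": self.se_method,
        }


def _assemble(
    profiles: Sequence[CSPProfile], dataset: TitrationDataset
) -> list[tuple[int, np.ndarray, np.ndarray, np.ndarray]]:
    """Per residue: (residue_id, Pt, Lt, Δd_obs) at usable points."""
    Pt = np.array([p.protein_total for p in dataset.points])
    Lt = np.array([p.ligand_total for p in dataset.points])
    blocks = []
    for prof in profiles:
        mask = prof.usable & np.isfinite(prof.d_values)
        n_titr = int(np.sum(mask & (Lt > 0)))
        if n_titr < 3:
            raise ValueError(
                f"residue {prof.residue_id}: need >= 3 usable points with "
                f"ligand present, got {n_titr}"
            )
        blocks.append((prof.residue_id, Pt[mask], Lt[mask], prof.d_values[mask]))
    return blocks


def _fit_blocks(
    blocks: Sequence[tuple[int, np.ndarray, np.ndarray, np.ndarray]],
    init: Mapping[str, float] | None = None,
) -> BindingFitResult:
    init = dict(init or {})
    params = lmfit.Parameters()
    all_lt = np.concatenate([b[2] for b in blocks])
    kd0 = init.get("Kd", float(np.median(all_lt[all_lt > 0])))
    params.add("Kd", value=kd0, min=1e-9)
    for rid, _, _, dobs in blocks:
        d_last = float(dobs[-1])
        d0 = init.get(f"dmax_{rid}", 1.2 * d_last if d_last > 0 else 1e-4)
        params.add(f"dmax_{rid}", value=max(d0, 1e-9), min=0.0)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        kd = p["Kd"].value
        res = []
        for rid, pt, lt, dobs in blocks:
            res.append(dobs - binding_isotherm(pt, lt, kd, p[f"dmax_{rid}"].value))
        return np.concatenate(res)

    n_vars = len(params)
    minres = lmfit.minimize(
        residual,
        params,
        method="leastsq",
        xtol=_XTOL,
        ftol=_XTOL,
        max_nfev=_MAX_ITER * (n_vars + 1),
    )
    resid = np.asarray(minres.residual)
    rss = float(np.sum(resid**2))
    kd_hat = float(minres.params["Kd"].value)
    warning = None
    kd_se = minres.params["Kd"].stderr
    if kd_se is None or not np.isfinite(kd_se):
        kd_se = float("inf")
        warning = "singular information matrix; covariance SE unavailable"
    dmax_hat, dmax_se = {}, {}
    for rid, *_ in blocks:
        par = minres.params[f"dmax_{rid}"]
        dmax_hat[rid] = float(par.value)
        dmax_se[rid] = float(par.stderr) if par.stderr is not None else float("inf")
    return BindingFitResult(
        Kd_hat=kd_hat,
        Kd_se=float(kd_se),
        dmax_hat=dmax_hat,
        dmax_se=dmax_se,
        residuals=resid,
        rss=rss,
        converged=bool(minres.success),
        n_obs=int(resid.size),
        applicability=_applicability(kd_hat),
        se_warning=warning,
    )


def fit_individual(
    profile: CSPProfile,
    dataset: TitrationDataset,
    init: Mapping[str, float] | None = None,
) -> BindingFitResult:
    """Fit (Kd, Δd_max) to one residue's Δd profile.

    Initial values default to Kd₀ = median nonzero [L]t and
    Δd_max,₀ = 1.2 × the last observed Δd; both are scale-free and land in
    the curved region of the isotherm for any sensibly designed series.
    Non-convergence is reported via ``converged=False``, not raised.
    """
    blocks = _assemble([profile], dataset)
    return _fit_blocks(blocks, init)


def fit_global(
    profiles: Sequence[CSPProfile],
    dataset: TitrationDataset,
    init: Mapping[str, float] | None = None,
) -> BindingFitResult:
    """Simultaneous fit over several residues sharing a single Kd.

    One Δd_max per residue, uniform weighting of all observations.  With a
    single profile this reduces exactly to :func:`fit_individual`.
    """
    if not profiles:
        raise ValueError("no profiles to fit")
    blocks = _assemble(profiles, dataset)
    return _fit_blocks(blocks, init)


def estimate_uncertainty(
    fit: BindingFitResult,
    profiles: Sequence[CSPProfile],
    dataset: TitrationDataset,
    method: str = "covariance",
    n_boot: int = 200,
    seed: int = 0,
) -> BindingFitResult:
    """Re-estimate the Kd standard error of a converged fit.

    ``covariance``
        SE from the residual-variance-scaled Gauss–Newton covariance — this
        is what the fit already carries; returned unchanged apart from the
        method label.
    ``bootstrap``
        Residual resampling: residuals of the fit are resampled with
        replacement onto the fitted curve, the model is refit ``n_boot``
        times, and the SE is the standard deviation of Kd over replicates.
        Fully determined by ``seed``.
    """
    if not fit.converged:
        raise ValueError("uncertainty estimation requires a converged fit")
    if method == "covariance":
        return replace(fit, se_method="covariance")
    if method != "bootstrap":
        raise ValueError(f"unknown method {method!r}")
    blocks = _assemble(profiles, dataset)
    fitted = np.concatenate(
        [
            binding_isotherm(pt, lt, fit.Kd_hat, fit.dmax_hat[rid])
            for rid, pt, lt, _ in blocks
        ]
    )
    resid = np.asarray(fit.residuals)
    rng = np.random.default_rng(seed)
    kds = []
    for _ in range(n_boot):
        boot_obs = fitted + rng.choice(resid, size=resid.size, replace=True)
        boot_blocks = []
        offset = 0
        for rid, pt, lt, dobs in blocks:
            boot_blocks.append((rid, pt, lt, boot_obs[offset : offset + dobs.size]))
            offset += dobs.size
        boot_fit = _fit_blocks(boot_blocks, init={"Kd": fit.Kd_hat})
        if boot_fit.converged:
            kds.append(boot_fit.Kd_hat)
    se = float(np.std(kds, ddof=1)) if len(kds) > 1 else float("inf")
    return replace(fit, Kd_se=se, se_method="bootstrap")
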