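"""Cross-method affinity comparison and the end-to-end pipeline.

An :class:`AffinityRecord` holds one ligand × method Kd cell of a
comparison table (NMR, fluorescence anisotropy, ITC); a cell may be marked
not-applicable when a method detected no specific binding.
:func:`fold_ratio` compares two ligands within one method with quadrature
error propagation.

:func:`run_pipeline` drives simulate → CSP → fit (plus optional FA and
trace analyses) from one structured config with a single root seed;
per-stage seeds are derived by stable hashing so the whole report is a pure
function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import math
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from titrakit import binding_fit, csp_mapping, fluorescence, synthetic_data, traj_geometry

__all__ = ["AffinityRecord", "fold_ratio", "run_pipeline", "derive_seed"]

_METHODS = ("NMR", "FA", "ITC")


@dataclass(frozen=True)
class AffinityRecord:
    """One Kd entry of a ligand × method affinity table."""

    ligand: str
    method: str  # NMR | FA | ITC
    Kd: float | None  # μM; None = not applicable (no specific binding)
    Kd_err: float | None = None  # μM
    note: str = ""

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.Kd is not None and self.Kd <= 0:
            raise ValueError("Kd must be > 0 or None (n.a.)")


def fold_ratio(a: AffinityRecord, b: AffinityRecord) -> tuple[float, float]:
    """Kd(a)/Kd(b) within one method, with quadrature-propagated error.

    Returns ``(ratio, ratio_err)``; the error is NaN when either record
    lacks one.  Records of different methods, or n.a. cells, cannot be
    compared.
    """
    if a.method != b.method:
        raise ValueError(f"method mismatch: {a.method} vs {b.method}")
    if a.Kd is None or b.Kd is None:
        raise ValueError("cannot form a ratio with an n.a. affinity")
    ratio = a.Kd / b.Kd
    if a.Kd_err is None or b.Kd_err is None:
        return ratio, float("nan")
    rel = math.hypot(a.Kd_err / a.Kd, b.Kd_err / b.Kd)
    return ratio, ratio * rel


def derive_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, derived from the root seed."""
    return zlib.crc32(f"{root_seed}:{stage}".encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# pipeline

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "titration", "fa", "traj", "affinity_table"},
    "titration": {
        "protein_total_uM", "true_Kd_uM", "n_points", "max_fold_Kd",
        "noise_H_ppm", "noise_N_ppm", "alpha", "fit_mode", "n_fit_residues",
    },
    "fa": {
        "protein_total_uM", "true_Kd_uM", "r_free", "r_bound", "n_points",
        "max_fold_Kd", "noise_r", "nonspecific", "intensity_slope",
    },
    "traj": {
        "mean_bound_dwell_ns", "mean_unbound_dwell_ns", "bound_level_A",
        "unbound_level_A", "level_noise_A", "dt_ns", "duration_ns",
        "threshold_low_A", "threshold_high_A", "min_dwell_ns", "censor_last",
    },
}


def _check_schema(config: Mapping[str, Any]) -> None:
    for key in config:
        if key not in _SCHEMA[""]:
            raise ValueError(f"unknown config key: '{key}'")
        if key in _SCHEMA and isinstance(config[key], Mapping):
            for sub in config[key]:
                if sub not in _SCHEMA[key]:
                    raise ValueError(f"unknown config key: '{key}.{sub}'")


def _config_hash(config: Mapping[str, Any]) -> str:
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and return (and optionally write) a report.

    The report embeds the config hash and root seed; identical
    (config, seed) produce identical numeric output.  Unknown config keys
    are rejected with the offending path.
    """
    _check_schema(config)
    root_seed = int(config.get("seed", 0))
    report: dict[str, Any] = {
        "config_hash": _config_hash(config),
        "seed": root_seed,
    }

    if "titration" in config:
        c = dict(config["titration"])
        kd = float(c.get("true_Kd_uM", 123.0))
        pt = float(c.get("protein_total_uM", 270.0))
        series = synthetic_data.design_ligand_series(
            pt, kd, int(c.get("n_points", 12)), float(c.get("max_fold_Kd", 10.0))
        )
        design = synthetic_data.TitrationDesign(
            protein_total=pt,
            ligand_points=series,
            residues=synthetic_data.galectin_demo_residues(),
            true_Kd=kd,
            noise_H=float(c.get("noise_H_ppm", synthetic_data.DEFAULT_NOISE_H)),
            noise_N=float(c.get("noise_N_ppm", synthetic_data.DEFAULT_NOISE_N)),
            seed=derive_seed(root_seed, "titration"),
        )
        dataset = synthetic_data.simulate_titration(design)
        alpha = float(c.get("alpha", csp_mapping.DEFAULT_ALPHA))
        profiles = csp_mapping.csp_profiles(dataset, alpha)
        classes = csp_mapping.classify_perturbed(profiles)
        n_fit = int(c.get("n_fit_residues", 9))
        top_ids = [cl.residue_id for cl in classes[:n_fit]]
        by_id = {p.residue_id: p for p in profiles}
        mode = c.get("fit_mode", "global")
        if mode == "global":
            fit = binding_fit.fit_global([by_id[i] for i in top_ids], dataset)
        elif mode == "individual":
            fit = binding_fit.fit_individual(by_id[top_ids[0]], dataset)
        else:
            raise ValueError(f"unknown config value titration.fit_mode='{mode}'")
        report["titration"] = {
            "true_Kd_uM": kd,
            "fit": fit.report(),
            "classification": [
                {
                    "residue_id": cl.residue_id,
                    "residue_name": cl.residue_name,
                    "d_final_ppm": None if np.isnan(cl.final_d) else round(cl.final_d, 6),
                    "class": cl.level.value,
                    "rank": cl.rank,
                }
                for cl in classes
            ],
        }

    if "fa" in config:
        c = dict(config["fa"])
        kd = float(c.get("true_Kd_uM", 35.2))
        pt = float(c.get("protein_total_uM", 3.0))
        nonspecific = bool(c.get("nonspecific", False))
        points = synthetic_data.design_ligand_series(
            pt, kd, int(c.get("n_points", 12)), float(c.get("max_fold_Kd", 30.0))
        )
        series = synthetic_data.simulate_fa_titration(
            protein_total=pt,
            true_Kd=math.inf if nonspecific else kd,
            r_free=float(c.get("r_free", 0.10)),
            r_bound=float(c.get("r_bound", 0.20)),
            ligand_points=points,
            noise_r=float(c.get("noise_r", 0.002)),
            intensity_slope=float(c.get("intensity_slope", -2e-4 if nonspecific else 0.0)),
            seed=derive_seed(root_seed, "fa"),
        )
        verdict = fluorescence.test_specific_binding(series)
        entry: dict[str, Any] = {
            "true_Kd_uM": None if nonspecific else kd,
            "specific": verdict.specific,
            "criterion": verdict.criterion,
        }
        if verdict.specific:
            fit = fluorescence.fit_one_site(series, deplete=True)
            entry["fit"] = {
                "Kd_uM": fit.Kd,
                "Kd_se_uM": fit.Kd_se,
                "r_free": fit.r_free,
                "r_bound": fit.r_bound,
            }
        report["fa"] = entry

    if "traj" in config:
        c = dict(config["traj"])
        design = synthetic_data.TelegraphDesign(
            mean_bound_dwell=float(c.get("mean_bound_dwell_ns", 730.0)),
            mean_unbound_dwell=float(c.get("mean_unbound_dwell_ns", 50.0)),
            bound_level=float(c.get("bound_level_A", 5.0)),
            unbound_level=float(c.get("unbound_level_A", 30.0)),
            level_noise=float(c.get("level_noise_A", 1.0)),
            dt=float(c.get("dt_ns", 0.1)),
            duration=float(c.get("duration_ns", 50_000.0)),
            seed=derive_seed(root_seed, "traj"),
        )
        trace = synthetic_data.simulate_distance_trace(design)
        segs = traj_geometry.segment_bound_states(
            trace,
            float(c.get("threshold_low_A", 10.0)),
            float(c.get("threshold_high_A", 20.0)),
            float(c.get("min_dwell_ns", 1.0)),
        )
        stats = traj_geometry.residence_stats(
            segs, censor_last=bool(c.get("censor_last", True))
        )
        report["traj"] = {"true_mean_bound_dwell_ns": design.mean_bound_dwell, **stats}

    if "affinity_table" in config:
        records = [
            AffinityRecord(
                ligand=row["ligand"],
                method=row["method"],
                Kd=row.get("Kd_uM"),
                Kd_err=row.get("Kd_err_uM"),
                note=row.get("note", ""),
            )
            for row in config["affinity_table"]
        ]
        table = [
            {
                "ligand": r.ligand,
                "method": r.method,
                "Kd_uM": r.Kd if r.Kd is not None else "n.a.",
                "Kd_err_uM": r.Kd_err,
                "note": r.note,
            }
            for r in records
        ]
        ratios = []
        by_method: dict[str, list[AffinityRecord]] = {}
        for r in records:
            if r.Kd is not None:
                by_method.setdefault(r.method, []).append(r)
        for method, recs in by_method.items():
            for i, a in enumerate(recs):
                for b in recs[i + 1 :]:
                    if a.ligand == b.ligand:
                        continue
                    weak, tight = (a, b) if a.Kd >= b.Kd else (b, a)
                    ratio, err = fold_ratio(weak, tight)
                    ratios.append(
                        {
                            "method": method,
                            "weaker": weak.ligand,
                            "tighter": tight.ligand,
                            "fold": round(ratio, 4),
                            "fold_err": None if math.isnan(err) else round(err, 4),
                        }
                    )
        report["affinity_table"] = table
        report["fold_ratios"] = ratios

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
        if "titration" in report:
            lines = ["residue_id\tresidue_name\td_final_ppm\tclass\trank"]
            for row in report["titration"]["classification"]:
                d = "" if row["d_final_ppm"] is None else f"{row['d_final_ppm']:.5f}"
                lines.append(
                    f"{row['residue_id']}\t{row['residue_name']}\t{d}\t"
                    f"{row['class']}\t{row['rank']}"
                )
            (out / "classification.tsv").write_text("\n".join(lines) + "\n")
    return report
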