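"""Reading, validation and writing of titration peak tables.

A titration dataset is an ordered series of titration points.  Each point
carries the total protein and ligand concentrations (μM internally) and one
amide cross-peak position (δH, δN in ppm) per assigned residue.  The first
point must be the apo reference (ligand_total = 0); every residue present in
the reference appears in every later point, if necessary with a
``missing``/``overlapped`` quality flag so that downstream profile building
can skip it explicitly instead of silently.

Two text dialects are supported:

``long_csv``
    one row per (point, residue) with explicit concentrations per row::

        point_index,protein_total_uM,ligand_total_uM,residue_id,residue_name,delta_H_ppm,delta_N_ppm,quality

``wide_csv``
    one row per residue, one δH/δN column pair per point (``dH:0,dN:0,...``);
    per-point concentrations live in ``#``-prefixed header lines.

Both writers emit metadata as ``# key = value`` header lines.  Concentrations
are μM throughout the package; an optional ``concentration_units`` metadata
key (``uM`` or ``mM``) converts on read.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "Quality",
    "PeakPosition",
    "TitrationPoint",
    "TitrationDataset",
    "read_peak_table",
    "write_peak_table",
    "write_structure_mapping",
]

#: ppm windows outside which an "ok" amide peak position is rejected
DELTA_H_RANGE = (-2.0, 15.0)
DELTA_N_RANGE = (90.0, 140.0)

_LONG_COLUMNS = [
    "point_index",
    "protein_total_uM",
    "ligand_total_uM",
    "residue_id",
    "residue_name",
    "delta_H_ppm",
    "delta_N_ppm",
    "quality",
]


class Quality(str, Enum):
    """Peak usability flag: ``ok`` peaks carry evidence, others are holes."""

    OK = "ok"
    OVERLAPPED = "overlapped"
    MISSING = "missing"


@dataclass(frozen=True)
class PeakPosition:
    """One amide cross peak of one residue at one titration point."""

    residue_id: int
    residue_name: str
    delta_H: float  # ppm
    delta_N: float  # ppm
    quality: Quality = Quality.OK

    def __post_init__(self) -> None:
        if self.quality is Quality.OK:
            lo, hi = DELTA_H_RANGE
            if not (lo <= self.delta_H <= hi):
                raise ValueError(
                    f"residue {self.residue_id}: delta_H={self.delta_H} ppm "
                    f"outside [{lo}, {hi}]"
                )
            lo, hi = DELTA_N_RANGE
            if not (lo <= self.delta_N <= hi):
                raise ValueError(
                    f"residue {self.residue_id}: delta_N={self.delta_N} ppm "
                    f"outside [{lo}, {hi}]"
                )


@dataclass
class TitrationPoint:
    """One point of the titration: concentrations plus peaks by residue."""

    index: int
    protein_total: float  # μM
    ligand_total: float  # μM
    peaks: dict[int, PeakPosition] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protein_total <= 0:
            raise ValueError(f"point {self.index}: protein_total must be > 0")
        if self.ligand_total < 0:
            raise ValueError(f"point {self.index}: ligand_total must be >= 0")


@dataclass
class TitrationDataset:
    """Ordered titration series with free-text metadata.

    The first point is the apo reference (``ligand_total == 0``) and points
    are strictly ordered by ligand concentration.
    """

    points: list[TitrationPoint]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.points:
            raise ValueError("dataset has no titration points")
        if self.points[0].ligand_total != 0:
            raise ValueError(
                "first titration point must be the apo reference "
                f"(ligand_total=0), got {self.points[0].ligand_total} μM"
            )
        lts = [p.ligand_total for p in self.points]
        if any(b <= a for a, b in zip(lts, lts[1:])):
            raise ValueError(f"ligand_total must be strictly increasing, got {lts}")
        ref_ids = set(self.points[0].peaks)
        for p in self.points[1:]:
            absent = ref_ids - set(p.peaks)
            for rid in absent:  # pad holes explicitly
                name = self.points[0].peaks[rid].residue_name
                p.peaks[rid] = PeakPosition(
                    rid, name, math.nan, math.nan, Quality.MISSING
                )

    @property
    def residue_ids(self) -> list[int]:
        """Residues tracked in the apo reference, ascending."""
        return sorted(self.points[0].peaks)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TitrationDataset):
            return NotImplemented
        if self.metadata != other.metadata or len(self.points) != len(other.points):
            return False
        for a, b in zip(self.points, other.points):
            if (a.index, a.protein_total, a.ligand_total) != (
                b.index,
                b.protein_total,
                b.ligand_total,
            ):
                return False
            if set(a.peaks) != set(b.peaks):
                return False
            for rid, pa in a.peaks.items():
                pb = b.peaks[rid]
                if (pa.residue_id, pa.residue_name, pa.quality) != (
                    pb.residue_id,
                    pb.residue_name,
                    pb.quality,
                ):
                    return False
                for x, y in ((pa.delta_H, pb.delta_H), (pa.delta_N, pb.delta_N)):
                    same = (math.isnan(x) and math.isnan(y)) or math.isclose(
                        x, y, rel_tol=0, abs_tol=1e-9
                    )
                    if not same:
                        return False
        return True


# ---------------------------------------------------------------------------
# reading


def _as_stream(source: str | TextIO) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    return io.StringIO(source)


def _split_header(stream: TextIO) -> tuple[dict[str, str], str]:
    """Pull '# key = value' lines off the top; return (metadata, body)."""
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    for line in stream:
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                meta[key.strip()] = value.strip()
        else:
            body_lines.append(line)
    return meta, "".join(body_lines)


def _unit_factor(meta: Mapping[str, str]) -> float:
    units = meta.get("concentration_units", "uM")
    try:
        return {"uM": 1.0, "mM": 1000.0}[units]
    except KeyError:
        raise ValueError(f"unknown concentration_units {units!r} (use uM or mM)")


def _parse_shift(raw: object) -> tuple[float, bool]:
    """Return (value, parsed_ok); blanks and non-numbers become NaN holes."""
    try:
        v = float(raw)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return math.nan, False
    if math.isnan(v):
        return math.nan, False
    return v, True


def read_peak_table(
    source: str | TextIO, dialect: str = "long_csv"
) -> TitrationDataset:
    """Parse a peak table into a validated :class:`TitrationDataset`.

    Parameters
    ----------
    source
        Text content or an open text stream in the declared dialect.
    dialect
        ``"long_csv"`` or ``"wide_csv"`` (module docstring describes both).

    Rows whose shifts do not parse are kept with ``quality=missing``.  A
    missing apo point or a residue duplicated within one point is a hard
    error.
    """
    meta, body = _split_header(_as_stream(source))
    factor = _unit_factor(meta)
    meta = {
        k: v
        for k, v in meta.items()
        if k not in ("concentration_units", "protein_total_uM", "ligand_total_uM")
    }
    if dialect == "long_csv":
        points = _read_long(body, factor)
    elif dialect == "wide_csv":
        points = _read_wide(body, meta, factor)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not points or points[0].ligand_total != 0:
        raise ValueError("no apo reference point (ligand_total = 0) in table")
    return TitrationDataset(points=points, metadata=meta)


def _read_long(body: str, factor: float) -> list[TitrationPoint]:
    df = pd.read_csv(io.StringIO(body), dtype=str, skip_blank_lines=True)
    missing_cols = [c for c in _LONG_COLUMNS if c not in df.columns and c != "quality"]
    if missing_cols:
        raise ValueError(f"long_csv table lacks required column(s): {missing_cols}")
    points: list[TitrationPoint] = []
    for idx, grp in df.groupby(df["point_index"].astype(int), sort=True):
        pt_conc = float(grp["protein_total_uM"].iloc[0]) * factor
        lt_conc = float(grp["ligand_total_uM"].iloc[0]) * factor
        peaks: dict[int, PeakPosition] = {}
        for _, row in grp.iterrows():
            rid = int(row["residue_id"])
            if rid in peaks:
                raise ValueError(f"residue {rid} duplicated at point {idx}")
            dh, ok_h = _parse_shift(row["delta_H_ppm"])
            dn, ok_n = _parse_shift(row["delta_N_ppm"])
            declared = str(row.get("quality", "ok") or "ok")
            if declared not in Quality._value2member_map_:
                raise ValueError(f"unknown quality flag {declared!r}")
            quality = Quality(declared)
            if not (ok_h and ok_n):
                quality = Quality.MISSING
            peaks[rid] = PeakPosition(rid, str(row["residue_name"]), dh, dn, quality)
        points.append(TitrationPoint(int(idx), pt_conc, lt_conc, peaks))
    return points


def _read_wide(
    body: str, meta: dict[str, str], factor: float
) -> list[TitrationPoint]:
    raw_meta_pt = meta.pop("_protein_totals", None)
    raw_meta_lt = meta.pop("_ligand_totals", None)
    df = pd.read_csv(io.StringIO(body), dtype=str, skip_blank_lines=True)
    if "residue_id" not in df.columns:
        raise ValueError("wide_csv table lacks required column(s): ['residue_id']")
    pair_idx = sorted(
        int(c.split(":", 1)[1]) for c in df.columns if c.startswith("dH:")
    )
    if not pair_idx:
        raise ValueError("wide_csv table has no dH:<i>/dN:<i> column pairs")
    if raw_meta_pt is None or raw_meta_lt is None:
        raise ValueError(
            "wide_csv table lacks '# _protein_totals = ...' / "
            "'# _ligand_totals = ...' concentration header lines"
        )
    pts = [float(x) * factor for x in raw_meta_pt.split(",")]
    lts = [float(x) * factor for x in raw_meta_lt.split(",")]
    if len(pts) != len(pair_idx) or len(lts) != len(pair_idx):
        raise ValueError(
            f"concentration headers list {len(pts)}/{len(lts)} values for "
            f"{len(pair_idx)} points"
        )
    points: list[TitrationPoint] = []
    for k, i in enumerate(pair_idx):
        peaks: dict[int, PeakPosition] = {}
        for _, row in df.iterrows():
            rid = int(row["residue_id"])
            if rid in peaks:
                raise ValueError(f"residue {rid} duplicated at point {i}")
            dh, ok_h = _parse_shift(row.get(f"dH:{i}"))
            dn, ok_n = _parse_shift(row.get(f"dN:{i}"))
            q_col = row.get(f"quality:{i}")
            declared = str(q_col) if isinstance(q_col, str) and q_col else "ok"
            quality = Quality(declared)
            if not (ok_h and ok_n):
                quality = Quality.MISSING
            peaks[rid] = PeakPosition(
                rid, str(row.get("residue_name", "UNK")), dh, dn, quality
            )
        points.append(TitrationPoint(k, pts[k], lts[k], peaks))
    return points


# ---------------------------------------------------------------------------
# writing


def _fmt(x: float) -> str:
    # repr gives the shortest decimal that round-trips the float exactly
    return "" if math.isnan(x) else repr(float(x))


def write_peak_table(dataset: TitrationDataset, dialect: str = "long_csv") -> str:
    """Serialize a dataset; inverse of :func:`read_peak_table` field-for-field."""
    lines = [f"# {k} = {v}" for k, v in sorted(dataset.metadata.items())]
    if dialect == "long_csv":
        lines.append(",".join(_LONG_COLUMNS))
        for p in dataset.points:
            for rid in sorted(p.peaks):
                pk = p.peaks[rid]
                lines.append(
                    f"{p.index},{_fmt(p.protein_total)},{_fmt(p.ligand_total)},"
                    f"{pk.residue_id},{pk.residue_name},{_fmt(pk.delta_H)},"
                    f"{_fmt(pk.delta_N)},{pk.quality.value}"
                )
    elif dialect == "wide_csv":
        n = len(dataset.points)
        lines.append(
            "# _protein_totals = "
            + ",".join(_fmt(p.protein_total) for p in dataset.points)
        )
        lines.append(
            "# _ligand_totals = "
            + ",".join(_fmt(p.ligand_total) for p in dataset.points)
        )
        header = ["residue_id", "residue_name"]
        for i in range(n):
            header += [f"dH:{i}", f"dN:{i}", f"quality:{i}"]
        lines.append(",".join(header))
        for rid in dataset.residue_ids:
            name = dataset.points[0].peaks[rid].residue_name
            row = [str(rid), name]
            for p in dataset.points:
                pk = p.peaks[rid]
                row += [_fmt(pk.delta_H), _fmt(pk.delta_N), pk.quality.value]
            lines.append(",".join(row))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PDB structure mapping


def write_structure_mapping(
    per_residue_values: Mapping[int, float],
    pdb_in: str,
    scale: str = "raw",
) -> str:
    """Write per-residue values into the B-factor column of a PDB text.

    Used to color structures by perturbation: every atom of a residue in
    ``per_residue_values`` gets that residue's (optionally percentile-scaled)
    value in columns 61–66; residues absent from the map get 0.00.  All other
    columns pass through byte-identically.

    ``scale="percentile"`` maps values to their percentile rank in [0, 100]
    so that heat scales are comparable across datasets.
    """
    if not per_residue_values:
        raise ValueError("per_residue_values is empty")
    values = dict(per_residue_values)
    if scale == "percentile":
        rids = list(values)
        arr = np.asarray([values[r] for r in rids], dtype=float)
        from scipy.stats import rankdata

        ranks = rankdata(arr, method="average")
        pct = (
            np.full_like(ranks, 100.0)
            if len(ranks) == 1
            else (ranks - 1.0) / (len(ranks) - 1.0) * 100.0
        )
        values = {r: p for r, p in zip(rids, pct)}
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")

    out_lines: list[str] = []
    touched: set[int] = set()
    for line in pdb_in.splitlines(keepends=True):
        if line.startswith(("ATOM  ", "HETATM")) and len(line.rstrip("\n")) >= 66:
            resseq = int(line[22:26])
            b = values.get(resseq, 0.0)
            if resseq in values:
                touched.add(resseq)
            line = line[:60] + f"{b:6.2f}" + line[66:]
        out_lines.append(line)
    if not touched:
        raise ValueError(
            "no residue in per_residue_values matches any PDB residue number"
        )
    return "".join(out_lines)
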