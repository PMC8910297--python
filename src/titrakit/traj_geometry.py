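"""Geometry post-processing of binding/unbinding trajectories.

Operates on the reduced observables an MD analysis produces rather than on
trajectory files: a uniformly sampled protein–ligand distance trace is
segmented into bound-state intervals with a hysteresis threshold pair, and
the interval durations give residence-time statistics.  Signed dihedral
angles and circular means handle interglycosidic torsion analysis, where a
naive arithmetic mean of angles near ±180° is meaningless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceTrace",
    "BoundSegments",
    "segment_bound_states",
    "residence_stats",
    "dihedral",
    "circular_mean",
]


@dataclass
class DistanceTrace:
    """Uniformly sampled protein–ligand distance time series (ns, Å)."""

    t: np.ndarray
    distance: np.ndarray
    dt: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)
        if self.t.shape != self.distance.shape:
            raise ValueError("t and distance must have equal length")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def duration(self) -> float:
        return float(self.t.size * self.dt)


@dataclass
class BoundSegments:
    """Disjoint, ordered bound-state intervals of one trace."""

    segments: list[tuple[float, float]]  # (start ns, end ns), end exclusive
    threshold_low: float
    threshold_high: float
    trace_start: float
    trace_end: float

    def durations(self) -> np.ndarray:
        return np.array([e - s for s, e in self.segments])


def _hysteresis_states(d: np.ndarray, low: float, high: float) -> np.ndarray:
    """Boolean bound/unbound per sample; between thresholds keeps state."""
    sig = np.zeros(d.size, dtype=np.int8)
    sig[d < low] = 1
    sig[d > high] = -1
    # initial state: bound only if already under the entry threshold
    if sig[0] == 0:
        sig[0] = -1
    # forward-fill nonzero signals
    idx = np.arange(d.size)
    idx[sig == 0] = 0
    idx = np.maximum.accumulate(idx)
    return sig[idx] == 1


def segment_bound_states(
    trace: DistanceTrace,
    threshold_low: float,
    threshold_high: float,
    min_dwell: float = 0.0,
) -> BoundSegments:
    """Hysteresis segmentation of a distance trace into bound intervals.

    The system enters the bound state when the distance drops below
    ``threshold_low`` and leaves it only above ``threshold_high``; the dead
    band in between suppresses flicker from level noise.  With equal
    thresholds this degrades to single-threshold crossing.  Afterwards,
    unbound gaps shorter than ``min_dwell`` are closed (merging their
    neighbours) and bound segments still shorter than ``min_dwell`` are
    dropped.
    """
    if threshold_low > threshold_high:
        raise ValueError("threshold_low must be <= threshold_high")
    if min_dwell < 0:
        raise ValueError("min_dwell must be >= 0")
    d = trace.distance
    if np.all(np.isnan(d)):
        raise ValueError("trace is all-NaN")
    bound = _hysteresis_states(d, threshold_low, threshold_high)

    padded = np.concatenate(([False], bound, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]  # sample indices, end exclusive
    t0 = float(trace.t[0])
    segs = [
        (t0 + s * trace.dt, t0 + e * trace.dt) for s, e in zip(starts, ends)
    ]

    if min_dwell > 0 and segs:
        merged = [segs[0]]
        for s, e in segs[1:]:
            ps, pe = merged[-1]
            if s - pe < min_dwell:  # close short unbound gap
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        segs = [(s, e) for s, e in merged if e - s >= min_dwell]

    return BoundSegments(
        segments=segs,
        threshold_low=threshold_low,
        threshold_high=threshold_high,
        trace_start=t0,
        trace_end=t0 + trace.duration,
    )


def residence_stats(segments: BoundSegments, censor_last: bool = False) -> dict:
    """Residence-time statistics of bound intervals.

    ``censor_last=True`` drops a final segment that abuts the end of the
    trace: its dwell was interrupted by the end of the simulation, not by a
    dissociation event, and including it biases the mean.  Returns a dict
    with ``mean_ns``, ``median_ns``, ``n_events`` and
    ``total_bound_fraction`` (the latter always over all segments).  An
    empty event list yields NaN statistics, not an exception.
    """
    if not segments.segments:
        raise ValueError("no bound segments")
    segs = list(segments.segments)
    total_bound = sum(e - s for s, e in segs)
    span = segments.trace_end - segments.trace_start
    if censor_last and segs and math.isclose(
        segs[-1][1], segments.trace_end, rel_tol=0, abs_tol=1e-9
    ):
        segs = segs[:-1]
    durations = np.array([e - s for s, e in segs])
    if durations.size == 0:
        return {
            "mean_ns": float("nan"),
            "median_ns": float("nan"),
            "n_events": 0,
            "total_bound_fraction": total_bound / span,
        }
    return {
        "mean_ns": float(durations.mean()),
        "median_ns": float(np.median(durations)),
        "n_events": int(durations.size),
        "total_bound_fraction": total_bound / span,
    }


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle of four points, degrees in (−180, 180].

    IUPAC sign convention: looking from p2 towards p3, the far bond rotated
    clockwise from the near bond is positive; cis = 0°.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if np.linalg.norm(b2) < 1e-12:
        raise ValueError("p2 and p3 coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 * (np.linalg.norm(b1) * np.linalg.norm(b2) + 1e-30):
        raise ValueError("p1, p2, p3 are collinear; dihedral undefined")
    if np.linalg.norm(n2) < 1e-10 * (np.linalg.norm(b2) * np.linalg.norm(b3) + 1e-30):
        raise ValueError("p2, p3, p4 are collinear; dihedral undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def circular_mean(angles) -> float:
    """Circular mean of angles in degrees, mapped to (−180, 180].

    Computed as atan2 of the mean sine and cosine; undefined (raises) when
    the resultant vector is shorter than 1e-8, i.e. the angles are balanced
    around the circle.
    """
    a = np.radians(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("empty angle list")
    s, c = float(np.mean(np.sin(a))), float(np.mean(np.cos(a)))
    if math.hypot(s, c) < 1e-8:
        raise ValueError("circular mean undefined: resultant length ~ 0")
    ang = math.degrees(math.atan2(s, c))
    if ang <= -180.0:
        ang += 360.0
    return ang
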