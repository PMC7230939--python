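"""Per-track and per-class motility statistics for cell-cluster trajectories.

Retinal neuroblasts (RNBs) cross the μOS channel array as clusters of
varying size.  Three size classes are distinguished: single cells
(1–2 cells), small clusters (3–5 cells, the preferentially motile
configuration) and large clusters (>5 cells).  For each track the
standard chemotaxis summary statistics are computed:

* total path length ``L_T`` — the sum of Euclidean step distances;
* net displacement ``D_N`` — the straight-line distance from the first
  to the last point (so ``L_T >= D_N`` always);
* directionality ratio ``DR`` — the cosine of the angle between the
  track's *net displacement vector* and the gradient axis, averaged
  over tracks.  One angle per trajectory, so a straight run toward the
  source scores 1 and unbiased jitter averages to 0.

Tracks whose net displacement is exactly zero have no defined angle;
they are excluded from DR and reported separately.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SizeClass",
    "TrackPoint",
    "ClusterTrack",
    "DirectionalityResult",
    "classify_cluster",
    "track_size_class",
    "total_path_length",
    "net_displacement",
    "directionality",
    "summarize_by_class",
    "MigrationSummary",
]


class SizeClass(IntEnum):
    """Cluster size classes: 1–2, 3–5 and >5 cells partition the integers."""

    SINGLE = 0
    SMALL = 1
    LARGE = 2


def classify_cluster(size: int) -> SizeClass:
    """Size class of a cluster of ``size`` cells (single 1–2, small 3–5, large >5)."""
    if int(size) != size or size < 1:
        raise ValueError(f"cluster size must be an integer >= 1, got {size}")
    if size <= 2:
        return SizeClass.SINGLE
    if size <= 5:
        return SizeClass.SMALL
    return SizeClass.LARGE


@dataclass(frozen=True)
class TrackPoint:
    """One observation of a cluster: time (h), position (µm), size (cells)."""

    t: float
    x: float
    y: float
    size: int

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("t must be >= 0")
        if int(self.size) != self.size or self.size < 1:
            raise ValueError("size must be an integer >= 1")


@dataclass
class ClusterTrack:
    """A time-ordered trajectory of one cluster with per-frame size.

    ``parent_id`` links fission children to the track they detached
    from; the child's first frame is its birth frame.
    """

    track_id: str
    t: np.ndarray      # hours, strictly increasing
    x: np.ndarray      # µm
    y: np.ndarray      # µm
    size: np.ndarray   # cells, integer >= 1
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.size = np.asarray(self.size, dtype=int)
        n = len(self.t)
        if n < 2:
            raise ValueError(f"track {self.track_id}: needs >= 2 points, got {n}")
        if not (len(self.x) == len(self.y) == len(self.size) == n):
            raise ValueError(f"track {self.track_id}: ragged point arrays")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(f"track {self.track_id}: t must be strictly increasing")
        if np.any(self.size < 1):
            raise ValueError(f"track {self.track_id}: sizes must be >= 1")

    @property
    def n_points(self) -> int:
        return len(self.t)

    def points(self) -> list[TrackPoint]:
        return [TrackPoint(t=float(t), x=float(x), y=float(y), size=int(s))
                for t, x, y, s in zip(self.t, self.x, self.y, self.size)]

    def size_at(self, t: float) -> int:
        """Size at frame time ``t`` (must be within the track's span)."""
        if t < self.t[0] - 1e-9 or t > self.t[-1] + 1e-9:
            raise ValueError(f"t={t} outside track {self.track_id} span")
        idx = int(np.searchsorted(self.t, t + 1e-9)) - 1
        return int(self.size[max(idx, 0)])

    def cumulative_path(self) -> np.ndarray:
        """Path length accumulated up to each frame (starts at 0)."""
        steps = np.hypot(np.diff(self.x), np.diff(self.y))
        return np.concatenate([[0.0], np.cumsum(steps)])


def track_size_class(track: ClusterTrack) -> SizeClass:
    """Whole-track class: mode of the per-frame classes, ties toward larger.

    A disaggregating track that spends most frames at 3–5 cells is
    summarized as SMALL even if it started larger; the per-frame
    classification remains available for timeline analyses.
    """
    classes = np.array([classify_cluster(int(s)) for s in track.size], dtype=int)
    counts = np.bincount(classes, minlength=3)
    best = np.flatnonzero(counts == counts.max())
    return SizeClass(int(best.max()))


def total_path_length(track: ClusterTrack) -> float:
    """Total path length L_T (µm): sum of consecutive-frame step distances."""
    return float(np.hypot(np.diff(track.x), np.diff(track.y)).sum())


def net_displacement(track: ClusterTrack) -> float:
    """Net displacement D_N (µm): Euclidean first-to-last-point distance."""
    return float(np.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0]))


@dataclass(frozen=True)
class DirectionalityResult:
    """Mean directionality with the bookkeeping of excluded tracks."""

    value: float          # mean cos(theta) over eligible tracks, in [-1, 1]
    n_used: int
    n_stationary: int     # tracks with D_N = 0, excluded (theta undefined)

    def __float__(self) -> float:
        return self.value


def _net_cosines(tracks: Sequence[ClusterTrack], axis: tuple[float, float]) -> tuple[np.ndarray, int]:
    ax = np.asarray(axis, dtype=float)
    norm = np.hypot(*ax)
    if norm == 0:
        raise ValueError("axis must be a nonzero vector")
    ax = ax / norm
    cosines, n_stationary = [], 0
    for tr in tracks:
        vx, vy = tr.x[-1] - tr.x[0], tr.y[-1] - tr.y[0]
        d = np.hypot(vx, vy)
        if d == 0:
            n_stationary += 1
            continue
        cosines.append((vx * ax[0] + vy * ax[1]) / d)
    return np.asarray(cosines), n_stationary


def directionality(tracks: Sequence[ClusterTrack],
                   axis: tuple[float, float] = (1.0, 0.0)) -> DirectionalityResult:
    """Directionality ratio DR: mean cosine between net displacements and ``axis``.

    The angle is taken per trajectory from its net-displacement vector.
    Stationary tracks (D_N = 0) are excluded and counted; an empty
    eligible set raises ``ValueError``.
    """
    cosines, n_stationary = _net_cosines(tracks, axis)
    if cosines.size == 0:
        raise ValueError("no track with nonzero net displacement; DR undefined")
    return DirectionalityResult(
        value=float(cosines.mean()),
        n_used=int(cosines.size),
        n_stationary=n_stationary,
    )


#: Per-class summary table; rows indexed by SizeClass name.
MigrationSummary = pd.DataFrame


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    if values.size == 0:
        return (np.nan, np.nan)
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return mean, se


def summarize_by_class(tracks: Sequence[ClusterTrack],
                       axis: tuple[float, float] = (1.0, 0.0)) -> MigrationSummary:
    """Per-class track counts, percentages and mean ± SE of L_T, D_N and DR.

    The SE denominator is the number of tracks in the class; for DR only
    tracks with nonzero net displacement contribute (their count is
    reported as ``n_directional``).
    """
    # canonical order makes the result exactly independent of input order
    tracks = sorted(tracks, key=lambda tr: str(tr.track_id))
    if not tracks:
        raise ValueError("need at least one track")
    rows = {}
    total = len(tracks)
    by_class: dict[SizeClass, list[ClusterTrack]] = {c: [] for c in SizeClass}
    for tr in tracks:
        by_class[track_size_class(tr)].append(tr)
    for cls in SizeClass:
        members = by_class[cls]
        lt = np.array([total_path_length(tr) for tr in members])
        dn = np.array([net_displacement(tr) for tr in members])
        if members:
            cosines, n_stat = _net_cosines(members, axis)
        else:
            cosines, n_stat = np.array([]), 0
        lt_m, lt_se = _mean_se(lt)
        dn_m, dn_se = _mean_se(dn)
        dr_m, dr_se = _mean_se(cosines)
        rows[cls.name] = {
            "n_tracks": len(members),
            "percent": 100.0 * len(members) / total,
            "lt_mean_um": lt_m, "lt_se_um": lt_se,
            "dn_mean_um": dn_m, "dn_se_um": dn_se,
            "dr_mean": dr_m, "dr_se": dr_se,
            "n_directional": int(cosines.size),
            "n_stationary": n_stat,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
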