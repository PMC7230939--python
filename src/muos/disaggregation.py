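"""Cluster fission (disaggregation) detection and timeline analysis.

Large RNB clusters (>5 cells) migrating through the channel array can
split into smaller collectives, preferentially of 3–5 cells.  This
module detects those fission events from parent-linked tracks, locates
them within the concentration-gradient regions of the channel, and
computes the timeline of the small-cluster fraction among motile
clusters — the signature of progressive disaggregation.

Cell count is conserved through every fission: the child sizes at a
split must sum to the parent's size at that frame, and violations raise
:class:`ConservationError` rather than being silently accepted.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import ClusterTrack, classify_cluster, SizeClass
from .transport import GradientRegions

__all__ = [
    "FissionEvent",
    "TimelineBin",
    "ConservationError",
    "detect_fission_events",
    "events_by_region",
    "timeline_fraction_small",
    "lineage_path_length",
    "is_en_masse",
]


class ConservationError(ValueError):
    """Child sizes at a fission do not sum to the parent's size."""


@dataclass(frozen=True)
class FissionEvent:
    """One cluster split: parent, time, place and the child partition."""

    parent_track_id: str
    t: float                      # hours
    position: tuple[float, float]  # (x, y) µm
    parent_size: int
    child_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.child_sizes) < 2:
            raise ValueError("a fission event needs >= 2 children")
        if sum(self.child_sizes) != self.parent_size:
            raise ConservationError(
                f"child sizes {self.child_sizes} do not sum to parent size {self.parent_size}"
            )


@dataclass(frozen=True)
class TimelineBin:
    """Fraction of motile clusters that are small (3–5 cells) at time ``t``."""

    t: float
    fraction_small: float
    n_motile: int

    def __post_init__(self) -> None:
        if self.n_motile > 0 and not 0.0 <= self.fraction_small <= 1.0:
            raise ValueError("fraction_small must lie in [0, 1]")


def _index_tracks(tracks: Sequence[ClusterTrack]) -> dict[str, ClusterTrack]:
    by_id: dict[str, ClusterTrack] = {}
    for tr in tracks:
        if tr.track_id in by_id:
            raise ValueError(f"duplicate track id {tr.track_id!r}")
        by_id[tr.track_id] = tr
    return by_id


def detect_fission_events(tracks: Sequence[ClusterTrack]) -> list[FissionEvent]:
    """Reconstruct fission events from parent-linked tracks.

    Children sharing a parent and a birth frame form one event; the
    event is located at the parent's position at that frame.  Children
    whose sizes do not sum to the parent's size there raise
    :class:`ConservationError`.  Tracks without parent links yield an
    empty list.
    """
    by_id = _index_tracks(tracks)
    groups: dict[tuple[str, float], list[ClusterTrack]] = {}
    for tr in tracks:
        if tr.parent_id is None:
            continue
        if tr.parent_id not in by_id:
            raise ValueError(f"track {tr.track_id}: unknown parent {tr.parent_id!r}")
        groups.setdefault((tr.parent_id, float(tr.t[0])), []).append(tr)

    events = []
    for (parent_id, t_birth), children in sorted(groups.items()):
        parent = by_id[parent_id]
        parent_size = parent.size_at(t_birth)
        child_sizes = tuple(int(c.size[0]) for c in
                            sorted(children, key=lambda c: c.track_id))
        if sum(child_sizes) != parent_size:
            raise ConservationError(
                f"fission of {parent_id} at t={t_birth}: children {child_sizes} "
                f"do not sum to parent size {parent_size}"
            )
        i = int(np.searchsorted(parent.t, t_birth + 1e-9)) - 1
        events.append(FissionEvent(
            parent_track_id=parent_id,
            t=t_birth,
            position=(float(parent.x[i]), float(parent.y[i])),
            parent_size=parent_size,
            child_sizes=child_sizes,
        ))
    return events


def events_by_region(events: Sequence[FissionEvent],
                     regions: GradientRegions) -> dict[str, int]:
    """Count fission events per gradient region (by axial position).

    Events outside the channel span are counted under ``"OUTSIDE"``.
    """
    counts = {"L": 0, "M": 0, "H": 0, "OUTSIDE": 0}
    for ev in events:
        counts[regions.locate(ev.position[0])] += 1
    return counts


def lineage_path_length(track: ClusterTrack, t: float,
                        by_id: dict[str, ClusterTrack]) -> float:
    """Cumulative path (µm) up to time ``t`` including the ancestor chain.

    A fission child is part of a moving cluster from the start of the
    recording, so its motility is judged on the path accumulated along
    its whole lineage, not just since its birth.
    """
    def segment(tr: ClusterTrack, up_to: float) -> float:
        sel = tr.t <= up_to + 1e-9
        return float(np.hypot(np.diff(tr.x[sel]), np.diff(tr.y[sel])).sum())

    path = segment(track, t)
    parent_id, birth = track.parent_id, float(track.t[0])
    guard = 0
    while parent_id is not None:
        parent = by_id.get(parent_id)
        if parent is None:
            break
        path += segment(parent, birth)
        parent_id, birth = parent.parent_id, float(parent.t[0])
        guard += 1
        if guard > 1000:
            raise ValueError("parent-link cycle detected")
    return path


def _fission_times(tracks: Sequence[ClusterTrack]) -> dict[str, float]:
    """Earliest child-birth time per parent id."""
    out: dict[str, float] = {}
    for tr in tracks:
        if tr.parent_id is not None:
            t0 = float(tr.t[0])
            out[tr.parent_id] = min(out.get(tr.parent_id, np.inf), t0)
    return out


def timeline_fraction_small(tracks: Sequence[ClusterTrack],
                            times: Sequence[float],
                            motility_threshold_um: float = 4.0,
                            channel_span: Optional[tuple[float, float]] = None
                            ) -> list[TimelineBin]:
    """Fraction of motile clusters with current size 3–5 at each time.

    A cluster is *motile* once its lineage path length exceeds
    ``motility_threshold_um`` (default 4 µm, one cell diameter — single
    cells jittering less than that never qualify).  A parent is counted
    up to, but not at, its fission time (its children stand in for it
    from then on).  If ``channel_span`` is given, clusters are counted
    only while their centroid x lies within it.
    """
    by_id = _index_tracks(tracks)
    fission_at = _fission_times(tracks)
    bins = []
    for t in times:
        n_small = n_motile = 0
        for tr in tracks:
            if t < tr.t[0] - 1e-9 or t > tr.t[-1] + 1e-9:
                continue
            t_fission = fission_at.get(tr.track_id)
            if t_fission is not None and t >= t_fission - 1e-9:
                continue  # replaced by its children
            if channel_span is not None:
                i = int(np.searchsorted(tr.t, t + 1e-9)) - 1
                if not channel_span[0] <= tr.x[max(i, 0)] <= channel_span[1]:
                    continue
            if lineage_path_length(tr, t, by_id) <= motility_threshold_um:
                continue
            n_motile += 1
            if classify_cluster(tr.size_at(t)) is SizeClass.SMALL:
                n_small += 1
        frac = n_small / n_motile if n_motile else np.nan
        bins.append(TimelineBin(t=float(t), fraction_small=frac, n_motile=n_motile))
    return bins


def is_en_masse(track: ClusterTrack, channel_length: float = 90.0) -> bool:
    """Whether a track crossed the whole channel (net displacement ≥ L_OS)."""
    from .metrics import net_displacement

    return net_displacement(track) >= channel_length
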