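"""Fission detection, region localization and the small-fraction timeline."""
import numpy as np
import pytest

from muos import (ClusterTrack, ConservationError, FissionEvent,
                  detect_fission_events, events_by_region, lineage_path_length,
                  is_en_masse, timeline_fraction_small)
from muos.synth import GeneratorConfig, generate_tracks, make_disaggregation_config


def fission_family(child_sizes=(5, 3), t_split=4.0):
    parent = ClusterTrack("p", t=np.arange(0, t_split + 1), x=np.arange(0, t_split + 1) * 2.0,
                          y=np.zeros(int(t_split) + 1), size=np.full(int(t_split) + 1, 8))
    children = [
        ClusterTrack(f"c{i}", t=np.arange(t_split, 9.0),
                     x=parent.x[-1] + np.arange(9 - t_split) * 1.5 + i,
                     y=np.zeros(9 - int(t_split)),
                     size=np.full(9 - int(t_split), s), parent_id="p")
        for i, s in enumerate(child_sizes)
    ]
    return [parent] + children


def test_detect_constructed_fission():
    tracks = fission_family()
    events = detect_fission_events(tracks)
    assert len(events) == 1
    ev = events[0]
    assert ev.parent_track_id == "p" and ev.t == 4.0
    assert sorted(ev.child_sizes) == [3, 5] and ev.parent_size == 8
    assert ev.position == (8.0, 0.0)  # parent's position at the split frame


def test_no_parent_links_gives_no_events():
    tracks = fission_family()
    unlinked = [ClusterTrack(t.track_id, t.t, t.x, t.y, t.size) for t in tracks]
    assert detect_fission_events(unlinked) == []


def test_conservation_violation_raises():
    tracks = fission_family(child_sizes=(5, 2))  # 5 + 2 != 8
    with pytest.raises(ConservationError):
        detect_fission_events(tracks)
    with pytest.raises(ConservationError):
        FissionEvent("p", 1.0, (0, 0), parent_size=8, child_sizes=(4, 3))
    with pytest.raises(ValueError, match=">= 2 children"):
        FissionEvent("p", 1.0, (0, 0), parent_size=8, child_sizes=(8,))


def test_zero_hazard_generates_zero_events():
    exp = generate_tracks(GeneratorConfig(seed=5, n_tracks=100,
                                          fission_base_hazard=0.0))
    assert exp.events == []
    assert detect_fission_events(exp.tracks) == []


def test_events_by_region_positions(regions):
    def ev(x):
        return FissionEvent("p", 2.0, (x, 250.0), 8, (5, 3))

    counts = events_by_region([ev(160.0), ev(225.0), ev(100.0), ev(195.0)], regions)
    assert counts == {"L": 1, "M": 1, "H": 1, "OUTSIDE": 1}
    assert sum(counts.values()) == 4


def test_ground_truth_events_fully_recovered(mid_profile):
    cfg = GeneratorConfig(seed=9, n_tracks=150, class_probs=(0.0, 0.2, 0.8),
                          fission_base_hazard=0.12, profile=mid_profile)
    exp = generate_tracks(cfg)
    assert len(exp.events) > 10
    detected = detect_fission_events(exp.tracks)
    truth = {(e.parent_track_id, e.t, tuple(sorted(e.child_sizes))) for e in exp.events}
    found = {(e.parent_track_id, e.t, tuple(sorted(e.child_sizes))) for e in detected}
    assert truth == found  # sensitivity 1.0 on linked synthetic data


def test_cell_count_conserved_through_fission_chains():
    cfg = GeneratorConfig(seed=21, n_tracks=120, class_probs=(0.0, 0.0, 1.0),
                          fission_base_hazard=0.3)
    exp = generate_tracks(cfg)
    assert len(exp.events) > 0
    by_parent = {}
    for tr in exp.tracks:
        by_parent.setdefault(tr.parent_id, []).append(tr)
    for root in by_parent.get(None, []):
        # leaves of the lineage tree: tracks with no children of their own
        def leaf_sizes(tr):
            kids = by_parent.get(tr.track_id, [])
            if not kids:
                return int(tr.size[-1])
            return sum(leaf_sizes(k) for k in kids)

        assert leaf_sizes(root) == int(root.size[0])


def test_timeline_all_small_clusters():
    tracks = [ClusterTrack(f"t{i}", t=np.arange(9.0),
                           x=np.arange(9.0) * 3.0, y=np.zeros(9),
                           size=np.full(9, 4)) for i in range(5)]
    bins = timeline_fraction_small(tracks, [2, 4, 8])
    assert all(b.fraction_small == 1.0 for b in bins)
    assert all(b.n_motile == 5 for b in bins)


def test_timeline_motility_threshold_excludes_jitter():
    slow = ClusterTrack("slow", t=np.arange(9.0), x=np.arange(9.0) * 0.3,
                        y=np.zeros(9), size=np.full(9, 4))
    fast = ClusterTrack("fast", t=np.arange(9.0), x=np.arange(9.0) * 3.0,
                        y=np.zeros(9), size=np.full(9, 7))
    bins = timeline_fraction_small([slow, fast], [8.0])
    assert bins[0].n_motile == 1 and bins[0].fraction_small == 0.0


def test_timeline_parent_not_double_counted():
    tracks = fission_family(t_split=4.0)
    bins = timeline_fraction_small(tracks, [3.0, 4.0, 6.0])
    # before the split: one large cluster; at and after: the two children
    assert bins[0].n_motile == 1 and bins[0].fraction_small == 0.0
    assert bins[1].n_motile == 2 and bins[1].fraction_small == 1.0
    assert bins[2].n_motile == 2


def test_fraction_small_rises_with_active_fission():
    # with a positive hazard and no aggregation the mean small fraction
    # can only go up; checked on the mean curve over 20 seeds
    curves = []
    for seed in range(20):
        cfg = GeneratorConfig(seed=seed, n_tracks=150,
                              class_probs=(0.0, 0.3, 0.7),
                              fission_base_hazard=0.1)
        exp = generate_tracks(cfg)
        bins = timeline_fraction_small(exp.tracks, [2.0, 4.0, 6.0, 8.0])
        curves.append([b.fraction_small for b in bins])
    mean_curve = np.nanmean(curves, axis=0)
    assert np.all(np.diff(mean_curve) > -0.02)
    assert mean_curve[-1] > mean_curve[0]


def test_lineage_path_includes_ancestors():
    tracks = fission_family(t_split=4.0)
    by_id = {t.track_id: t for t in tracks}
    child = by_id["c0"]
    own = float(np.hypot(np.diff(child.x), np.diff(child.y)).sum())
    parent_path = 8.0  # 4 steps of 2 µm
    assert lineage_path_length(child, 8.0, by_id) == pytest.approx(own + parent_path)
    assert lineage_path_length(child, 4.0, by_id) == pytest.approx(parent_path)


def test_en_masse_label():
    crossing = ClusterTrack("x", t=[0, 1], x=[0.0, 95.0], y=[0, 0], size=[8, 8])
    assert is_en_masse(crossing, channel_length=90.0)
    assert not is_en_masse(ClusterTrack("y", t=[0, 1], x=[0, 10], y=[0, 0],
                                        size=[8, 8]), channel_length=90.0)
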