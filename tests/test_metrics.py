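"""Track metrics: classification, path statistics, directionality, summaries."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from muos import (ClusterTrack, SizeClass, classify_cluster, directionality,
                  net_displacement, summarize_by_class, total_path_length,
                  track_size_class)
from muos.synth import GeneratorConfig, generate_tracks


def make_track(points, track_id="t0", size=4, parent=None):
    pts = np.asarray(points, dtype=float)
    return ClusterTrack(track_id=track_id, t=np.arange(len(pts), dtype=float),
                        x=pts[:, 0], y=pts[:, 1],
                        size=np.full(len(pts), size, dtype=int), parent_id=parent)


# ---------------------------------------------------------- classification

@pytest.mark.parametrize("size,expected", [
    (1, SizeClass.SINGLE), (2, SizeClass.SINGLE),
    (3, SizeClass.SMALL), (4, SizeClass.SMALL), (5, SizeClass.SMALL),
    (6, SizeClass.LARGE), (40, SizeClass.LARGE),
])
def test_classify_cluster_bounds(size, expected):
    assert classify_cluster(size) is expected


def test_classify_cluster_rejects_invalid():
    for bad in (0, -1, 2.5):
        with pytest.raises(ValueError):
            classify_cluster(bad)


@given(st.integers(min_value=1, max_value=1000))
def test_classes_partition_positive_integers(size):
    cls = classify_cluster(size)
    assert cls is {True: SizeClass.SINGLE,
                   False: SizeClass.SMALL if size <= 5 else SizeClass.LARGE}[size <= 2]


def test_track_class_is_mode_with_ties_toward_larger():
    tr = ClusterTrack("a", t=[0, 1, 2], x=[0, 1, 2], y=[0, 0, 0], size=[8, 4, 4])
    assert track_size_class(tr) is SizeClass.SMALL  # majority small
    tie = ClusterTrack("b", t=[0, 1, 2, 3], x=[0, 1, 2, 3], y=[0] * 4,
                       size=[8, 8, 4, 4])
    assert track_size_class(tie) is SizeClass.LARGE  # tie broken upward


# ------------------------------------------------------------ path metrics

def test_path_length_and_net_displacement_hand_values():
    tr = make_track([(0, 0), (3, 0), (3, 4)])
    assert total_path_length(tr) == pytest.approx(7.0)   # 3 + 4
    assert net_displacement(tr) == pytest.approx(5.0)    # 3-4-5 triangle


def test_stationary_and_loop_tracks():
    assert total_path_length(make_track([(1, 1), (1, 1), (1, 1)])) == 0.0
    loop = make_track([(0, 0), (5, 0), (5, 5), (0, 5), (0, 0)])
    assert net_displacement(loop) == 0.0
    straight = make_track([(0, 0), (2, 0), (4, 0)])
    assert total_path_length(straight) == net_displacement(straight)


@st.composite
def random_tracks(draw):
    n = draw(st.integers(2, 12))
    xs = draw(st.lists(st.floats(-100, 100), min_size=n, max_size=n))
    ys = draw(st.lists(st.floats(-100, 100), min_size=n, max_size=n))
    return make_track(list(zip(xs, ys)))


@given(random_tracks())
def test_path_length_dominates_net_displacement(track):
    assert total_path_length(track) >= net_displacement(track) - 1e-9


def test_track_validation():
    with pytest.raises(ValueError, match=">= 2 points"):
        make_track([(0, 0)])
    with pytest.raises(ValueError, match="strictly increasing"):
        ClusterTrack("x", t=[0, 0], x=[0, 1], y=[0, 1], size=[1, 1])
    with pytest.raises(ValueError, match=">= 1"):
        ClusterTrack("x", t=[0, 1], x=[0, 1], y=[0, 1], size=[1, 0])


# ---------------------------------------------------------- directionality

def test_dr_aligned_tracks():
    tracks = [make_track([(0, 0), (i + 1.0, 0)], track_id=f"t{i}") for i in range(4)]
    assert directionality(tracks).value == pytest.approx(1.0)


def test_dr_symmetric_compass_tracks():
    headings = [(1, 0), (0, 1), (-1, 0), (0, -1)]
    tracks = [make_track([(0, 0), h], track_id=f"t{i}") for i, h in enumerate(headings)]
    assert directionality(tracks).value == pytest.approx(0.0, abs=1e-12)


def test_dr_excludes_stationary_and_counts_them():
    tracks = [make_track([(0, 0), (1, 0)], track_id="moving"),
              make_track([(0, 0), (0, 0)], track_id="still")]
    res = directionality(tracks)
    assert res.n_used == 1 and res.n_stationary == 1
    with pytest.raises(ValueError, match="DR undefined"):
        directionality([make_track([(0, 0), (0, 0)])])


@given(st.lists(random_tracks(), min_size=1, max_size=8),
       st.floats(-50, 50), st.floats(-50, 50))
def test_dr_bounds_translation_invariance_axis_flip(tracks, dx, dy):
    # displacements at float-roundoff scale are not translation-stable
    movers = [t for t in tracks if net_displacement(t) > 1e-6]
    if not movers:
        return
    res = directionality(movers)
    assert -1.0 <= res.value <= 1.0
    shifted = [ClusterTrack(t.track_id, t.t, t.x + dx, t.y + dy, t.size)
               for t in movers]
    assert directionality(shifted).value == pytest.approx(res.value, abs=1e-5)
    assert directionality(movers, axis=(-1, 0)).value == pytest.approx(-res.value, abs=1e-12)


# --------------------------------------------------------------- summaries

def test_summary_one_track_per_class():
    tracks = [
        ClusterTrack("s", t=[0, 1], x=[0, 1], y=[0, 0], size=[1, 1]),
        ClusterTrack("m", t=[0, 1], x=[0, 2], y=[0, 0], size=[4, 4]),
        ClusterTrack("l", t=[0, 1], x=[0, 3], y=[0, 0], size=[8, 8]),
    ]
    summary = summarize_by_class(tracks)
    assert np.allclose(summary["percent"], 100 / 3)
    assert summary["percent"].sum() == pytest.approx(100.0, abs=0.5)
    assert (summary["lt_mean_um"] >= summary["dn_mean_um"] - 1e-9).all()


def test_summary_identical_tracks_have_zero_se():
    tracks = [make_track([(0, 0), (2, 1), (4, 0)], track_id=f"t{i}")
              for i in range(5)]
    summary = summarize_by_class(tracks)
    row = summary.loc["SMALL"]
    assert row["lt_se_um"] == 0.0 and row["dn_se_um"] == 0.0 and row["dr_se"] == 0.0


def test_summary_order_invariance():
    exp = generate_tracks(GeneratorConfig(seed=3, n_tracks=60))
    fwd = summarize_by_class(exp.tracks)
    rev = summarize_by_class(exp.tracks[::-1])
    assert fwd.equals(rev)


def test_summary_recovers_class_proportions():
    # published mix: ~65% of motile RNBs are small clusters
    exp = generate_tracks(GeneratorConfig(seed=11, n_tracks=300))
    summary = summarize_by_class(exp.tracks)
    assert abs(summary.loc["SMALL", "percent"] - 65.0) < 6.0


def test_summary_requires_tracks():
    with pytest.raises(ValueError):
        summarize_by_class([])
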