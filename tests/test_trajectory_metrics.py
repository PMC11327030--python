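"""Migration measures: hand-computable cases, invariances, cohort math."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gelquant import io as gio
from gelquant import synthetic_data as sd
from gelquant import trajectory_metrics as tm


def traj_from(points, frame_interval=10.0, frames=None, track_id="t"):
    return tm.Trajectory(track_id, frame_interval, np.asarray(points, float),
                         None if frames is None else np.asarray(frames))


@st.composite
def random_walks(draw):
    n = draw(st.integers(min_value=2, max_value=40))
    seed = draw(st.integers(min_value=0, max_value=2**31 - 1))
    rng = np.random.default_rng(seed)
    return traj_from(rng.normal(0, 3, size=(n, 2)).cumsum(axis=0))


# ---------------------------------------------------------------------------
# container validation
# ---------------------------------------------------------------------------


def test_trajectory_validation():
    with pytest.raises(ValueError):
        traj_from([(0, 0)])  # one point
    with pytest.raises(ValueError):
        traj_from([(0, 0), (1, 1)], frames=[1, 1])  # non-increasing frames
    with pytest.raises(ValueError):
        traj_from([(0, 0), (1, 1)], frame_interval=0)


# ---------------------------------------------------------------------------
# speed / persistence / static classification
# ---------------------------------------------------------------------------


def test_mean_speed_hand_cases():
    assert tm.mean_speed(traj_from([(0, 0), (0, 4)])) == pytest.approx(0.4)
    assert tm.mean_speed(traj_from([(5, 5), (5, 5), (5, 5)])) == 0.0
    steps = traj_from([(0, 0), (1, 0), (3, 0), (6, 0)])  # steps of 1, 2, 3 μm
    assert tm.mean_speed(steps) == pytest.approx(0.2)


def test_mean_speed_uses_elapsed_time_across_gaps():
    """A step spanning a 2-frame gap is divided by the true 20 min."""
    gapped = traj_from([(0, 0), (0, 4)], frames=[0, 2])
    assert tm.mean_speed(gapped) == pytest.approx(4 / 20)


def test_persistence_hand_cases():
    assert tm.persistence(traj_from([(0, 0), (1, 0), (2, 0)])) == 1.0
    loop = traj_from([(0, 0), (1, 0), (1, 1), (0, 0)])
    assert tm.persistence(loop) == 0.0
    right_angle = traj_from([(0, 0), (3, 0), (3, 4)])
    assert tm.persistence(right_angle) == pytest.approx(5 / 7)
    assert tm.persistence(traj_from([(2, 2), (2, 2)])) == 0.0  # 0/0 case


def test_static_classification_boundary_is_strict():
    params = tm.AnalysisParams()  # 75 μm = 1.5 × 50 μm cell diameter
    assert tm.classify_static(traj_from([(0, 0), (74.9, 0)]), params)
    assert not tm.classify_static(traj_from([(0, 0), (75.0, 0)]), params)
    assert tm.classify_static(traj_from([(1, 1), (1, 1)]), params)


@given(random_walks())
def test_persistence_is_a_fraction(traj):
    """Triangle inequality: net displacement never exceeds path length."""
    p = tm.persistence(traj)
    assert 0.0 <= p <= 1.0 + 1e-12
    assert tm.net_displacement(traj) <= tm.path_length(traj) + 1e-9


@given(random_walks(), st.floats(min_value=-np.pi, max_value=np.pi),
       st.floats(min_value=-100, max_value=100))
def test_mean_speed_rigid_motion_invariance(traj, angle, shift):
    rot = np.array([[np.cos(angle), -np.sin(angle)],
                    [np.sin(angle), np.cos(angle)]])
    moved = traj_from(traj.positions @ rot.T + shift)
    assert tm.mean_speed(moved) == pytest.approx(tm.mean_speed(traj), rel=1e-9)


# ---------------------------------------------------------------------------
# MSD and α
# ---------------------------------------------------------------------------


def test_msd_ballistic_closed_form():
    v, dt = 0.5, 10.0  # μm/min at 10-min frames
    t = np.arange(20)
    traj = traj_from(np.column_stack([v * t * dt, np.zeros(20)]))
    curve = tm.msd_curve(traj)
    np.testing.assert_allclose(curve.msd_um2, (v * curve.lags_min) ** 2, rtol=1e-12)


def test_msd_static_track_is_zero():
    curve = tm.msd_curve(traj_from([(1, 1)] * 12))
    assert curve.is_defined
    np.testing.assert_array_equal(curve.msd_um2, 0.0)


def test_msd_three_point_hand_computation():
    traj = traj_from([(0, 0), (1, 0), (2, 0)])
    curve = tm.msd_curve(traj, max_lag=2, min_pairs=1)
    np.testing.assert_allclose(curve.msd_um2, [1.0, 4.0])
    short = tm.msd_curve(traj_from([(0, 0), (1, 0)]))
    assert not short.is_defined  # too short: flagged, no exception


def test_msd_excludes_pairs_straddling_gaps():
    """Only frame pairs exactly ℓ apart contribute; gaps thin the average."""
    traj = traj_from([(0, 0), (1, 0), (3, 0), (4, 0)], frames=[0, 1, 3, 4])
    curve = tm.msd_curve(traj, max_lag=1, min_pairs=1)
    np.testing.assert_allclose(curve.msd_um2, [1.0])  # pairs (0,1) and (3,4)
    assert curve.n_pairs[0] == 2


def test_alpha_ballistic_is_two():
    t = np.arange(30, dtype=float)
    traj = traj_from(np.column_stack([2.0 * t, np.zeros(30)]))
    assert tm.alpha_exponent(tm.msd_curve(traj)) == pytest.approx(2.0, abs=1e-6)


def test_alpha_scale_invariance(rng):
    walk = traj_from(rng.normal(0, 2, size=(50, 2)).cumsum(axis=0))
    a1 = tm.alpha_exponent(tm.msd_curve(walk))
    scaled = traj_from(walk.positions * 37.5)
    a2 = tm.alpha_exponent(tm.msd_curve(scaled))
    assert a2 == pytest.approx(a1, abs=1e-9)


def test_alpha_undefined_for_flat_curve():
    assert np.isnan(tm.alpha_exponent(
        tm.msd_curve(traj_from([(1, 1)] * 12))))  # all-zero MSD dropped


# ---------------------------------------------------------------------------
# full track metrics and cohort summary
# ---------------------------------------------------------------------------


def test_track_metrics_ballistic():
    t = np.arange(11, dtype=float)
    m = tm.compute_track_metrics(traj_from(np.column_stack([t, np.zeros(11)])))
    assert m.path_length == pytest.approx(10.0)
    assert m.net_displacement == pytest.approx(10.0)
    assert m.persistence == pytest.approx(1.0)
    assert m.is_static  # 10 μm < 75 μm
    assert m.mean_speed == pytest.approx(0.1)


def test_track_metrics_static_track():
    m = tm.compute_track_metrics(traj_from([(3, 3)] * 12))
    assert m.mean_speed == 0.0
    assert m.persistence == 0.0
    assert m.is_static
    assert np.isnan(m.alpha)


def test_short_track_gets_undefined_alpha_but_other_metrics():
    m = tm.compute_track_metrics(traj_from([(0, 0), (10, 0), (20, 0)]))
    assert np.isnan(m.alpha)  # below min_track_frames
    assert m.mean_speed == pytest.approx(1.0)
    assert m.persistence == 1.0


def test_cohort_summary_fractions(rng):
    tracks = [traj_from([(0, 0), (0.1 * (i < 2) + 100 * (i >= 2), 0)],
                        track_id=str(i)) for i in range(10)]
    metrics = [tm.compute_track_metrics(t) for t in tracks]
    summary = tm.summarize_cohort(metrics, "test")
    assert summary.percent_static == pytest.approx(20.0)
    assert np.isnan(summary.mean_alpha)  # all two-point tracks: α undefined
    assert summary.n_tracks == 10
    with pytest.raises(ValueError):
        tm.summarize_cohort([], "empty")


def test_cohort_summary_matches_direct_recomputation(rng):
    """Summary of a mixed cohort equals recomputation from ground truth."""
    cfg = sd.SimConfig(seed=9)
    tracks = [sd.simulate_brownian_track(cfg, 2.0, rng=rng, track_id=str(i))
              for i in range(20)]
    tracks += [sd.simulate_persistent_track(cfg, 0.0, 1.0, rng=rng,
                                            track_id=f"s{i}") for i in range(5)]
    metrics = [tm.compute_track_metrics(t) for t in tracks]
    summary = tm.summarize_cohort(metrics, "mixed")
    assert summary.percent_static == pytest.approx(
        100 * np.mean([m.is_static for m in metrics]))
    assert summary.mean_instant_speed == pytest.approx(
        np.mean([tm.mean_speed(t) for t in tracks]))
    assert summary.percent_persistence == pytest.approx(
        100 * np.mean([tm.persistence(t) for t in tracks]))


def test_raising_threshold_never_decreases_percent_static(rng):
    tracks = [traj_from(rng.normal(0, 5, size=(30, 2)).cumsum(axis=0))
              for _ in range(30)]
    fractions = []
    for thr in (10, 75, 200, 1000):
        params = tm.AnalysisParams(static_threshold=thr)
        fractions.append(np.mean([tm.classify_static(t, params) for t in tracks]))
    assert all(a <= b for a, b in zip(fractions, fractions[1:]))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def test_read_tracks_csv_roundtrip(tmp_path, rng):
    tracks = [traj_from(rng.normal(0, 3, size=(5, 2)).cumsum(axis=0),
                        track_id=f"c{i}") for i in range(3)]
    path = gio.write_tracks_csv(tracks, tmp_path / "tracks.csv")
    back = tm.read_tracks(path, dialect="csv")
    assert len(back) == 3
    for orig, rt in zip(tracks, back):
        np.testing.assert_allclose(rt.positions, orig.positions, atol=1e-9)


def test_read_tracks_rejects_single_point_with_warning(tmp_path):
    (tmp_path / "t.csv").write_text(
        "track_id,frame,x_um,y_um\n"
        "a,0,0,0\na,1,1,1\na,2,2,2\n"
        "b,0,5,5\nb,1,6,6\nb,2,7,7\n"
        "lonely,0,9,9\n")
    with pytest.warns(UserWarning, match="fewer than 2"):
        tracks = tm.read_tracks(tmp_path / "t.csv")
    assert [t.track_id for t in tracks] == ["a", "b"]
    assert all(t.n_points == 3 for t in tracks)


def test_read_tracks_errors(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("track_id,frame,x_um\na,0,0\n")
    with pytest.raises(ValueError, match="missing required columns"):
        tm.read_tracks(p)
    p.write_text("track_id,frame,x_um,y_um\na,0,oops,0\na,1,1,1\n")
    with pytest.raises(ValueError, match="non-numeric"):
        tm.read_tracks(p)
    with pytest.raises(ValueError, match="unknown dialect"):
        tm.read_tracks(p, dialect="imaris")


def test_trackmate_xml_roundtrip(tmp_path, rng):
    tracks = [traj_from(rng.normal(0, 3, size=(6, 2)).cumsum(axis=0),
                        track_id=f"tm{i}") for i in range(2)]
    path = gio.write_trackmate_xml(
        tracks, tmp_path / "tracks.xml",
        detector_settings={"logThreshold": 0.3, "blobDiameter": 50.0})
    back = tm.read_tracks(path, dialect="trackmate_xml")
    assert len(back) == 2
    assert back[0].frame_interval == tracks[0].frame_interval
    for orig, rt in zip(tracks, back):
        np.testing.assert_allclose(rt.positions, orig.positions, atol=1e-9)
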