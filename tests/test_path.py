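"""Path metrics, behavioural-state classification, headsweep bias and
backtrack-and-redirect detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wavegait import CentroidTrack, ParameterError, PathParams, UndefinedResult, simulate_path
from wavegait import path as pb


def _track(xy_mm, angle=None, fps=30.0):
    xy = np.asarray(xy_mm, dtype=float)
    angle = np.full(xy.shape[0], 180.0) if angle is None else np.asarray(angle, float)
    return CentroidTrack(fps=fps, mm_per_px=1.0, xy=xy, angle_deg=angle)


class TestVelocityAndDistance:
    def test_stationary(self):
        track = _track(np.zeros((50, 2)))
        assert np.all(pb.instantaneous_velocity(track) == 0.0)
        assert pb.total_distance(track) == 0.0

    def test_uniform_motion(self):
        # 0.1 mm/frame at 30 fps -> 3.0 mm/s
        xy = np.column_stack([np.arange(50) * 0.1, np.zeros(50)])
        v = pb.instantaneous_velocity(_track(xy))
        np.testing.assert_allclose(v, 3.0, rtol=1e-12)

    def test_total_distance_steps(self):
        xy = np.column_stack([np.arange(11) * 0.5, np.zeros(11)])
        assert pb.total_distance(_track(xy)) == pytest.approx(5.0)

    def test_distance_scales_with_mm_per_px(self):
        xy = np.column_stack([np.arange(11) * 0.5, np.zeros(11)])
        t1 = CentroidTrack(fps=30, mm_per_px=1.0, xy=xy, angle_deg=np.full(11, 180.0))
        t2 = CentroidTrack(fps=30, mm_per_px=2.0, xy=xy, angle_deg=np.full(11, 180.0))
        assert pb.total_distance(t2) == pytest.approx(2 * pb.total_distance(t1))

    def test_simulated_mean_speed_recovered(self):
        """Mean instantaneous velocity matches the emitted speed profile's
        time average (and sits near the configured cruise speed)."""
        p = PathParams(seed=3)
        track, truth = simulate_path(p)
        v = pb.instantaneous_velocity(track)
        assert np.mean(v) == pytest.approx(p.mean_speed, rel=0.05)
        moving = truth.states != "still"
        assert np.mean(v[moving[:-1]]) > np.mean(v) - 0.1


class TestClassifyStates:
    def test_straight_bent_still(self):
        xy = np.column_stack([np.arange(6) * 0.1, np.zeros(6)])
        angle = np.array([180.0, 215.0, 150.0, 181.0, 100.0, 180.0])
        track = _track(xy, angle)
        s = pb.classify_states(track)
        assert s.states[0] == "straight"
        assert s.states[1] == "bent"
        assert s.headsweep[1] == "left"       # >= 210 deg
        assert s.headsweep[2] == "right"      # <= 150 deg
        assert s.states[4] == "bent"

    def test_still_overrides_angle(self):
        track = _track(np.zeros((10, 2)), np.full(10, 225.0))
        s = pb.classify_states(track)
        assert np.all(s.states == "still")
        assert np.all(s.headsweep == "left")  # flags independent of state

    def test_partition_property(self):
        p = PathParams(seed=9, headsweep_rate=0.5, pause_prob=0.05, duration=60.0)
        track, _ = simulate_path(p)
        s = pb.classify_states(track)
        props = s.proportions()
        assert sum(props.values()) == pytest.approx(1.0)
        assert set(np.unique(s.states)) <= {"straight", "bent", "still"}


class TestHeadsweepBias:
    def test_balanced_counts(self):
        est, p = pb.headsweep_bias(10, 10)
        assert est == pytest.approx(0.5)
        assert p > 0.9

    def test_one_sided_counts(self):
        est, p = pb.headsweep_bias(20, 0)
        assert est == 1.0
        assert p < 0.001

    def test_no_events_errors(self):
        with pytest.raises(ParameterError):
            pb.headsweep_bias(0, 0)

    def test_null_calibration(self, rng):
        """Unbiased animals: the bias test rejects at ~5%."""
        hits = 0
        reps = 500
        for _ in range(reps):
            left = int(rng.binomial(60, 0.5))
            _, p = pb.headsweep_bias(left, 60 - left)
            hits += p < 0.05
        assert 0.02 <= hits / reps <= 0.09


class TestCurviness:
    def test_straight_line(self):
        xy = np.column_stack([np.linspace(0, 10, 100), np.zeros(100)])
        assert pb.curviness(xy) == pytest.approx(1.0, abs=1e-12)

    def test_semicircle(self):
        theta = np.linspace(0.0, np.pi, 1001)
        xy = np.column_stack([np.cos(theta), np.sin(theta)])
        assert pb.curviness(xy) == pytest.approx(np.pi / 2, abs=1e-3)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        angle=st.floats(0.0, 2 * np.pi),
        scale=st.floats(0.1, 50.0),
        dx=st.floats(-100.0, 100.0),
    )
    def test_similarity_invariance(self, angle, scale, dx):
        rng = np.random.default_rng(0)
        xy = np.cumsum(rng.normal(size=(50, 2)), axis=0)
        c = np.cos(angle), np.sin(angle)
        rot = np.array([[c[0], -c[1]], [c[1], c[0]]])
        xy2 = scale * xy @ rot.T + np.array([dx, 1.0])
        assert pb.curviness(xy2) == pytest.approx(pb.curviness(xy), rel=1e-9)
        assert pb.curviness(xy2) >= 1.0

    def test_zero_net_displacement_undefined(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(UndefinedResult):
            pb.curviness(xy)


class TestAngleHistogram:
    def test_single_bin(self):
        track = _track(np.zeros((100, 2)), np.full(100, 185.0))
        counts, edges = pb.angle_histogram(track)
        assert counts.sum() == 100
        k = int(np.argmax(counts))
        assert edges[k] == 180.0 and edges[k + 1] == 190.0
        assert counts[k] == 100

    def test_uniform_angles_flat(self, rng):
        angles = rng.uniform(0.0, 360.0, 10_000)
        track = _track(np.zeros((10_000, 2)), angles)
        counts, _ = pb.angle_histogram(track)
        from scipy import stats

        p = stats.chisquare(counts).pvalue
        assert p > 0.01


class TestBacktrackDetector:
    def test_straight_path_no_episodes(self):
        p = PathParams(headsweep_rate=0, backtrack_rate=0, pause_prob=0,
                       heading_noise_sd_deg=0, angle_noise_sd_deg=0, duration=30.0)
        track, _ = simulate_path(p)
        assert pb.detect_backtrack_redirect(track) == []

    def test_single_injected_episode(self):
        p = PathParams(seed=21, backtrack_rate=0.02, duration=120.0,
                       headsweep_rate=0.0)
        track, truth = simulate_path(p)
        assert len(truth.backtrack_episodes) >= 1
        eps = pb.detect_backtrack_redirect(track)
        assert len(eps) == len(truth.backtrack_episodes)
        for det, (s, e, side) in zip(eps, truth.backtrack_episodes):
            assert det.first_turn == side
            assert det.start < e and det.end > s
            assert det.backtrack_mm > 0

    def test_mirror_reflection_flips_turn_labels(self):
        p = PathParams(seed=8, backtrack_rate=0.03, duration=120.0)
        track, _ = simulate_path(p)
        eps = pb.detect_backtrack_redirect(track)
        mirrored = CentroidTrack(
            fps=track.fps,
            mm_per_px=track.mm_per_px,
            xy=track.xy * np.array([1.0, -1.0]),
            angle_deg=360.0 - track.angle_deg,
        )
        eps_m = pb.detect_backtrack_redirect(mirrored)
        assert len(eps) == len(eps_m)
        flip = {"left": "right", "right": "left"}
        for a, b in zip(eps, eps_m):
            assert b.first_turn == flip[a.first_turn]
            assert (a.start, a.end) == (b.start, b.end)

    def test_sensitivity_and_fdr_on_labelled_paths(self):
        n_true = n_det = n_match = n_fp = 0
        for seed in range(12):
            p = PathParams(seed=seed, backtrack_rate=0.03, duration=120.0)
            track, truth = simulate_path(p)
            eps = pb.detect_backtrack_redirect(track)
            n_true += len(truth.backtrack_episodes)
            n_det += len(eps)
            matched = set()
            for det in eps:
                hit = False
                for i, (s, e, _) in enumerate(truth.backtrack_episodes):
                    if det.start < e and det.end > s:
                        matched.add(i)
                        hit = True
                if not hit:
                    n_fp += 1
            n_match += len(matched)
        assert n_true >= 20
        assert n_match / n_true >= 0.9
        assert n_fp / max(n_det, 1) <= 0.1
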