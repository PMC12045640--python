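"""Leg-speed, segmentation and phase estimators against analytic cases,
a brute-force threshold oracle and generator ground truth."""

import numpy as np
import pytest

from wavegait import GaitParams, ParameterError, RunConfig, simulate_gait
from wavegait import kinematics as kin
from wavegait.core import LEG_IDS, LegTrackTable, segment_of
from wavegait.events import pearson_r2

from conftest import make_velocity_series


def _table_from_xy(xy, fps=60.0, mm_per_px=0.01):
    return LegTrackTable(
        fps=fps, mm_per_px=mm_per_px, legs={leg: xy.copy() for leg in LEG_IDS}
    )


class TestLegSpeed:
    def test_stationary_leg_zero_speed(self):
        xy = np.tile([5.0, 5.0], (100, 1))
        vel = kin.leg_speed(_table_from_xy(xy))
        assert np.allclose(vel.speed["T1L"], 0.0)

    def test_uniform_motion_arithmetic(self):
        # 1 px/frame at 60 fps, 0.01 mm/px -> 0.6 mm/s
        xy = np.column_stack([np.arange(100.0), np.zeros(100)])
        vel = kin.leg_speed(_table_from_xy(xy))
        np.testing.assert_allclose(vel.speed["T2R"], 0.6, rtol=1e-9)

    def test_too_short_track_suggests_smaller_window(self):
        xy = np.zeros((4, 2))
        with pytest.raises(ParameterError, match="window"):
            kin.leg_speed(_table_from_xy(xy))

    def test_speed_peaks_inside_true_swings(self, fast_gait):
        """On simulated gait, >= 99% of per-cycle speed peaks fall inside
        ground-truth swing intervals."""
        truth, vel = fast_gait["truth"], fast_gait["vel"]
        hits = total = 0
        for leg in LEG_IDS:
            v = vel.speed[leg]
            mask = truth.swing_mask(leg, v.size)
            # peak within each true cycle window
            for (s, e) in truth.swing_frames[leg]:
                lo, hi = max(0, s - 3), min(v.size, e + 3)
                peak = lo + int(np.argmax(v[lo:hi]))
                total += 1
                hits += bool(mask[peak])
        assert hits / total >= 0.99


def brute_force_threshold_oracle(v, threshold, min_frames):
    """Single-threshold crossing segmentation (independent reference)."""
    runs, start = [], None
    for i, x in enumerate(v):
        if x >= threshold and start is None:
            start = i
        elif x < threshold and start is not None:
            if i - start >= min_frames:
                runs.append((start, i))
            start = None
    if start is not None and len(v) - start >= min_frames:
        runs.append((start, len(v)))
    return runs


class TestSegmentation:
    def test_all_zero_velocity_no_swings(self):
        vel = make_velocity_series([], 100)
        ss = kin.segment_swings(vel)
        assert all(len(v) == 0 for v in ss.swings.values())

    def test_square_pulses_match_threshold_oracle(self):
        """On noise-free pulse trains hysteresis segmentation equals the
        brute-force single-threshold oracle exactly."""
        # 0.07 s pulses every 0.2 s at 60 fps
        pulses = [(12 * k, 12 * k + 4) for k in range(20)]
        vel = make_velocity_series(pulses, 12 * 20 + 8, amplitude=8.0)
        ss = kin.segment_swings(vel)
        thr = 0.3 * np.percentile(vel.speed["T1L"], 95)
        expected = brute_force_threshold_oracle(vel.speed["T1L"], thr, 2)
        for leg in LEG_IDS:
            assert ss.swings[leg] == expected
        # within one frame of the constructed truth
        for (s, e), (ts, te) in zip(ss.swings["T1L"], pulses):
            assert abs(s - ts) <= 1 and abs(e - te) <= 1

    def test_short_runs_discarded(self):
        vel = make_velocity_series([(10, 11), (30, 36)], 60)
        ss = kin.segment_swings(vel)
        assert ss.swings["T1L"] == [(30, 36)]

    def test_frame_agreement_with_ground_truth(self, fast_gait):
        truth, ss = fast_gait["truth"], fast_gait["ss"]
        for leg in LEG_IDS:
            agree = np.mean(truth.swing_mask(leg, ss.n_frames) == ss.swing_mask(leg))
            assert agree >= 0.98


class TestDurationsAndPeriod:
    def test_stance_between_consecutive_swings(self):
        ss = kin.SwingStanceSeries(
            swings={leg: [] for leg in LEG_IDS} | {"T1L": [(3, 10), (25, 32)]},
            fps=100.0, n_frames=50,
        )
        st = kin.stance_durations(ss)
        np.testing.assert_allclose(st["T1L"], [0.15])
        assert st["T2L"].size == 0  # no swings -> no stances

    def test_single_swing_no_stance(self):
        ss = kin.SwingStanceSeries(
            swings={leg: [(0, 5)] for leg in LEG_IDS}, fps=100.0, n_frames=50
        )
        assert all(v.size == 0 for v in kin.stance_durations(ss).values())

    @pytest.mark.parametrize("period", [0.2, 0.7])
    def test_cycle_period_regular_onsets(self, period):
        fps = 100.0
        step = int(round(period * fps))
        swings = {leg: [(k * step, k * step + 5) for k in range(10)] for leg in LEG_IDS}
        ss = kin.SwingStanceSeries(swings=swings, fps=fps, n_frames=step * 10 + 10)
        assert kin.cycle_period(ss) == pytest.approx(period, rel=1e-9)

    def test_period_undefined_without_swings(self):
        from wavegait import UndefinedResult

        ss = kin.SwingStanceSeries(
            swings={leg: [] for leg in LEG_IDS}, fps=60.0, n_frames=100
        )
        with pytest.raises(UndefinedResult):
            kin.cycle_period(ss)

    def test_generator_stance_matches_construction(self):
        # T = 0.7, s_w = 0.07 -> stance 0.63 s, estimator error <= 1 frame
        table, truth, _ = simulate_gait(GaitParams(period=0.7, n_cycles=10, seed=4))
        vel = kin.leg_speed(table)
        ss = kin.segment_swings(vel)
        st = np.concatenate(list(kin.stance_durations(ss).values()))
        assert np.mean(st) == pytest.approx(0.63, abs=1.5 / table.fps)


class TestDutyCycles:
    def test_worked_example(self):
        swings = {leg: [(0, 5), (20, 25), (40, 45)] for leg in LEG_IDS}
        ss = kin.SwingStanceSeries(swings=swings, fps=100.0, n_frames=60)
        duty = kin.duty_cycles(ss, period=0.2)
        for seg in ("T1", "T2", "T3"):
            assert duty[seg][0] == pytest.approx(0.25)
            assert duty[seg][1] == pytest.approx(0.75)
            assert sum(duty[seg]) == pytest.approx(1.0)

    def test_stance_duty_rises_with_period(self):
        """Constant swing duration with increasing period: stance duty
        strictly increases, swing duty decreases."""
        swing_duties, stance_duties = [], []
        for i, T in enumerate([0.2, 0.3, 0.45, 0.7]):
            table, _, _ = simulate_gait(GaitParams(period=T, n_cycles=10, seed=10 + i))
            vel = kin.leg_speed(table)
            ss = kin.segment_swings(vel)
            period = kin.cycle_period(ss)
            duty = kin.duty_cycles(ss, period)
            swing_duties.append(np.mean([duty[s][0] for s in duty]))
            stance_duties.append(np.mean([duty[s][1] for s in duty]))
        assert np.all(np.diff(stance_duties) > 0)
        assert np.all(np.diff(swing_duties) < 0)


class TestStride:
    def test_known_displacement(self):
        xy = np.zeros((60, 2))
        xy[20:, 0] = 120.0  # 1.2 mm at 0.01 mm/px
        table = _table_from_xy(xy)
        ss = kin.SwingStanceSeries(
            swings={leg: [(15, 25)] for leg in LEG_IDS}, fps=60.0, n_frames=60
        )
        strides = kin.stride_length(table, ss)
        assert strides["T3L"][0] == pytest.approx(1.2)

    def test_zero_length_swing_zero_stride(self):
        xy = np.column_stack([np.arange(60.0), np.zeros(60)])
        table = _table_from_xy(xy)
        ss = kin.SwingStanceSeries(
            swings={leg: [(10, 10)] for leg in LEG_IDS}, fps=60.0, n_frames=60
        )
        assert kin.stride_length(table, ss)["T1L"][0] == 0.0

    def test_stride_speed_regression_linear(self):
        """Fixed stride gain across a speed sweep: stride regresses
        linearly on speed with r^2 > 0.9."""
        speeds, strides = [], []
        for i, sp in enumerate(np.linspace(0.8, 3.0, 8)):
            table, truth, _ = simulate_gait(
                GaitParams(speed=sp, n_cycles=8, seed=20 + i)
            )
            vel = kin.leg_speed(table)
            ss = kin.segment_swings(vel)
            st = np.concatenate(list(kin.stride_length(table, ss).values()))
            speeds.append(sp)
            strides.append(np.mean(st))
        r2, p = pearson_r2(np.array(speeds), np.array(strides))
        assert r2 > 0.9


class TestPhases:
    def _ss(self, onsets_by_leg, fps=1000.0):
        swings = {
            leg: [(int(round(t * fps)), int(round(t * fps)) + 5) for t in onsets]
            for leg, onsets in onsets_by_leg.items()
        }
        for leg in LEG_IDS:
            swings.setdefault(leg, [])
        n = max((e for v in swings.values() for _, e in v), default=10) + 10
        return kin.SwingStanceSeries(swings=swings, fps=fps, n_frames=n)

    def test_intraseg_identical_onsets_zero(self):
        on = [0.0, 0.2, 0.4]
        ss = self._ss({"T1L": on, "T1R": on})
        assert kin.intrasegmental_phase(ss, 0.2)["T1"] == pytest.approx(0.0, abs=1e-9)

    def test_intraseg_half_period_is_180(self):
        ss = self._ss({"T1L": [0.0, 0.2, 0.4], "T1R": [0.1, 0.3, 0.5]})
        assert kin.intrasegmental_phase(ss, 0.2)["T1"] == pytest.approx(180.0, abs=1e-6)

    def test_intraseg_missing_side_flagged_nan(self):
        ss = self._ss({"T1L": [0.0, 0.2]})
        assert np.isnan(kin.intrasegmental_phase(ss, 0.2)["T1"])

    def test_interseg_third_period_is_120(self):
        ss = self._ss({"T3L": [0.0, 0.3, 0.6], "T2L": [0.1, 0.4, 0.7]})
        phases = kin.intersegmental_phase(ss, 0.3, anchor="T3L")
        assert phases["T2"] == pytest.approx(120.0, abs=1e-6)
        assert phases["T3"] == pytest.approx(0.0, abs=1e-9)

    def test_phases_invariant_to_global_time_shift(self, fast_gait):
        ss = fast_gait["ss"]
        period = kin.cycle_period(ss)
        shift = 37
        shifted = kin.SwingStanceSeries(
            swings={
                leg: [(s + shift, e + shift) for s, e in ss.swings[leg]]
                for leg in LEG_IDS
            },
            fps=ss.fps,
            n_frames=ss.n_frames + shift,
        )
        a = kin.intersegmental_phase(ss, period)
        b = kin.intersegmental_phase(shifted, period)
        for seg in a:
            assert a[seg] == pytest.approx(b[seg], abs=1e-9)

    def test_dropout_inflates_intrasegmental_phase(self):
        """Swing dropout degrades left-right coordination as estimated
        downstream (the slow-walking phenotype)."""
        vals = {}
        for skip in (0.0, 0.3):
            phs = []
            for seed in range(8):
                table, _, _ = simulate_gait(
                    GaitParams(period=0.7, n_cycles=12, skip_prob=skip,
                               intraseg_jitter_sd_deg=10.0, seed=seed)
                )
                vel = kin.leg_speed(table)
                ss = kin.segment_swings(vel)
                period = kin.cycle_period(ss)
                phs.append(np.nanmean(list(kin.intrasegmental_phase(ss, period).values())))
            vals[skip] = np.mean(phs)
        assert vals[0.3] > vals[0.0]


class TestScaleInvariance:
    def test_period_duty_phase_invariant_to_spatial_scale(self, fast_gait):
        table = fast_gait["table"]
        rescaled = LegTrackTable(
            fps=table.fps,
            mm_per_px=table.mm_per_px * 3.0,
            legs={leg: table.legs[leg] / 3.0 for leg in LEG_IDS},
        )
        for t in (table, rescaled):
            vel = kin.leg_speed(t)
            ss = kin.segment_swings(vel)
            assert kin.cycle_period(ss) == pytest.approx(0.2, rel=0.02)
        s1 = kin.summarise(table)
        s2 = kin.summarise(rescaled)
        assert s1.period == pytest.approx(s2.period, rel=1e-9)
        for seg in s1.duty:
            assert s1.duty[seg][0] == pytest.approx(s2.duty[seg][0], rel=1e-9)
            assert s1.interseg_phase[seg] == pytest.approx(
                s2.interseg_phase[seg], abs=1e-9
            )
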