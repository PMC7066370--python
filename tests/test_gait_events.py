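"""Ankle-speed thresholds, the hysteresis automaton and step parameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stereogait import gait_events as ge
from stereogait.io_formats import COCO18_INDEX
from stereogait.stereo_geometry import SkeletonSeries3D


def skeleton_with_ankles(left, right, rate=30.0, valid=None):
    """Skeleton whose only meaningful joints are the two ankles."""
    T = len(left)
    xyz = np.zeros((T, 18, 3))
    xyz[:, COCO18_INDEX["LAnkle"]] = left
    xyz[:, COCO18_INDEX["RAnkle"]] = right
    v = np.ones((T, 18), dtype=bool) if valid is None else valid
    return SkeletonSeries3D(rate, xyz, v, "lab")


def speed(values, foot="right", rate=30.0, valid=None):
    v = np.asarray(values, dtype=float)
    ok = np.ones(len(v), bool) if valid is None else valid
    return ge.SpeedSeries(foot, rate, v, ok)


class TestAnkleSpeed:
    def test_static_ankle_gives_zeros(self):
        sk = skeleton_with_ankles(np.tile([1, 2, 0.1], (30, 1)),
                                  np.tile([0, 0, 0.1], (30, 1)))
        assert np.allclose(ge.ankle_speed(sk, "left").v, 0.0)

    def test_uniform_advance_gives_f_times_step(self):
        pos = np.outer(np.arange(30), [0.04, 0.0, 0.0])
        sk = skeleton_with_ankles(pos, np.zeros((30, 3)))
        v = ge.ankle_speed(sk, "left").v
        assert np.allclose(v, 1.2, atol=1e-12)  # 0.04 m/frame at 30 Hz

    def test_invalid_position_invalidates_adjacent_speeds(self):
        pos = np.outer(np.arange(30), [0.04, 0.0, 0.0])
        valid = np.ones((30, 18), bool)
        valid[10, COCO18_INDEX["LAnkle"]] = False
        sk = skeleton_with_ankles(pos, np.zeros((30, 3)), valid=valid)
        sp = ge.ankle_speed(sk, "left")
        assert not sp.valid[10] and not sp.valid[11]
        assert sp.valid[9] and sp.valid[12]

    def test_too_few_valid_frames_rejected(self):
        valid = np.zeros((30, 18), bool)
        valid[0, COCO18_INDEX["RAnkle"]] = True
        sk = skeleton_with_ankles(np.zeros((30, 3)), np.zeros((30, 3)), valid=valid)
        with pytest.raises(ValueError, match="fewer than 2"):
            ge.ankle_speed(sk, "right")

    def test_walking_mean_speed_matches_configuration(self, walk_gt):
        """Time-mean smoothed ankle speed over the walk ~ step_length*cadence/60."""
        from stereogait.pipeline_cli import skeleton_from_table
        from stereogait.sync_align import resample_series
        from stereogait.synthetic_gait import render_reference
        from conftest import NOISE_FREE_SCENE

        ref = render_reference(walk_gt, NOISE_FREE_SCENE)
        sk = skeleton_from_table(resample_series(ref, 30.0))
        sp = ge.smooth_speed(ge.ankle_speed(sk, "right"))
        cfg = walk_gt.gait
        t = np.arange(len(sp.v)) / 30.0
        # over whole strides (heel strike to heel strike) the mean ankle
        # speed equals the progression speed step_length * cadence / 60
        first_hs = walk_gt.heel_strikes["right"][0][0]
        last_hs = walk_gt.heel_strikes["right"][-1][0]
        inside = (t >= first_hs) & (t <= last_hs)
        expected = cfg.step_length * cfg.cadence / 60.0
        assert sp.v[inside].mean() == pytest.approx(expected, rel=0.05)


class TestThresholds:
    def test_nearest_rank_enumeration(self):
        th = ge.estimate_thresholds(speed(np.arange(1.0, 101.0)))
        assert th.high == 65.0
        assert th.low == pytest.approx(52.0, abs=1e-12)

    def test_low_is_exactly_eighty_percent_of_high(self):
        rng = np.random.default_rng(50)
        th = ge.estimate_thresholds(speed(rng.uniform(0.1, 3.0, 200)))
        assert th.low == pytest.approx(0.8 * th.high, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(20, 500), st.integers(0, 2**31 - 1))
    def test_percentile_fraction_within_one_over_n(self, n, seed_):
        v = np.random.default_rng(seed_).uniform(0.0, 5.0, n)
        if np.ptp(v) < 1e-9:
            return
        th = ge.estimate_thresholds(speed(v))
        frac = (v <= th.high).mean()
        assert abs(frac - 0.65) <= 1.0 / n + 1e-12

    def test_flat_record_rejected(self):
        with pytest.raises(ValueError, match="no gait dynamics"):
            ge.estimate_thresholds(speed(np.full(50, 1.0)))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 20"):
            ge.estimate_thresholds(speed(np.arange(10.0)))

    def test_scaling_speeds_scales_thresholds_and_keeps_states(self):
        rng = np.random.default_rng(51)
        v = np.abs(np.sin(np.arange(100) / 5.0)) * 2.0 + rng.uniform(0, 0.1, 100)
        th1 = ge.estimate_thresholds(speed(v))
        th2 = ge.estimate_thresholds(speed(v * 3.0))
        assert th2.high == pytest.approx(3.0 * th1.high, rel=1e-12)
        s1 = ge.detect_foot_states(speed(v), th1)
        s2 = ge.detect_foot_states(speed(v * 3.0), th2)
        assert (s1.states == s2.states).all()

    def test_crop_to_active_excludes_standing_phases(self):
        v = np.concatenate([np.full(100, 0.01), np.abs(np.sin(np.arange(90) / 4.0)) * 2,
                            np.full(50, 0.01)])
        cropped = ge.crop_to_active(speed(v))
        assert not cropped.valid[:99].any()
        assert not cropped.valid[191:].any()
        assert cropped.valid[100:190].sum() > 80


class TestFootStateAutomaton:
    def test_block_alternation_switches_at_boundaries(self):
        v = np.concatenate([np.zeros(10), np.full(10, 10.0)] * 3)
        th = ge.HysteresisThresholds(high=5.0, low=4.0)
        states = ge.detect_foot_states(speed(v), th).states
        expected = np.concatenate([np.zeros(10, int), np.ones(10, int)] * 3)
        assert (states == expected).all()

    def test_all_below_low_is_all_stance(self):
        th = ge.HysteresisThresholds(high=5.0, low=4.0)
        states = ge.detect_foot_states(speed(np.full(40, 1.0)), th).states
        assert (states == 0).all()

    def test_dip_into_band_holds_swing(self):
        v = np.concatenate([np.zeros(5), np.full(5, 10.0), np.full(5, 4.5),
                            np.full(5, 10.0), np.zeros(5)])
        th = ge.HysteresisThresholds(high=5.0, low=4.0)
        states = ge.detect_foot_states(speed(v), th).states
        assert (states[5:20] == 1).all()  # band dip does not end the swing

    def test_initial_state_follows_first_sample(self):
        th = ge.HysteresisThresholds(high=5.0, low=4.0)
        assert ge.detect_foot_states(speed(np.full(10, 10.0)), th).states[0] == 1
        assert ge.detect_foot_states(speed(np.full(10, 1.0)), th).states[0] == 0

    def test_invalid_frames_inherit_previous_state(self):
        v = np.concatenate([np.full(5, 10.0), np.zeros(3), np.full(5, 10.0)])
        valid = np.ones(13, bool)
        valid[5:8] = False
        th = ge.HysteresisThresholds(high=5.0, low=4.0)
        states = ge.detect_foot_states(speed(v, valid=valid), th).states
        assert (states == 1).all()

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_hysteresis_never_chatters_more_than_single_threshold(self, seed_):
        rng = np.random.default_rng(seed_)
        v = np.abs(rng.normal(1.0, 0.8, 150))
        th = ge.HysteresisThresholds(high=1.2, low=0.96)
        hyst = ge.detect_foot_states(speed(v), th).states
        single = (v > (th.high + th.low) / 2).astype(int)
        assert np.abs(np.diff(hyst)).sum() <= np.abs(np.diff(single)).sum()


class TestTrimIncomplete:
    def run(self, pattern):
        states = ge.FootStateSeries("left", 30.0, np.array(pattern))
        return ge.trim_incomplete(states)

    def test_enter_stance_exit_stance_keeps_all(self):
        cycles, case = self.run([0] * 5 + [1] * 5 + [0] * 5 + [1] * 5 + [0] * 5)
        assert case == 4
        assert cycles == [(10, 20)]

    def test_enter_swing_exit_swing_drops_boundary_partials(self):
        # partial steps at both window edges; the two interior cycles remain
        pattern = [1] * 3 + ([0] * 4 + [1] * 4) * 3
        cycles, case = self.run(pattern)
        assert case == 1
        assert cycles == [(3, 11), (11, 19)]

    def test_enter_stance_exit_swing_drops_last(self):
        pattern = [0] * 4 + [1] * 4 + [0] * 4 + [1] * 4 + [0] * 4 + [1] * 3
        cycles, case = self.run(pattern)
        assert case == 2
        assert cycles == [(8, 16)]

    def test_enter_swing_exit_stance_drops_leading_partial(self):
        # the truncated step before the first heel strike never forms a cycle
        pattern = [1] * 3 + [0] * 4 + [1] * 4 + [0] * 4
        cycles, case = self.run(pattern)
        assert case == 3
        assert cycles == [(3, 11)]

    def test_all_stance_yields_no_cycles(self):
        cycles, case = self.run([0] * 20)
        assert cycles == [] and case == 4


class TestComputeParameters:
    def build_states(self, events, total, foot, rate=30.0):
        """events: list of (toe_off_frame, heel_strike_frame) swings."""
        s = np.zeros(total, int)
        for to, hs in events:
            s[to:hs] = 1
        return ge.FootStateSeries(foot, rate, s)

    def test_hand_event_arithmetic(self):
        # L heel strikes at 1.0 s and 2.0 s, toe off at 1.6 s (30 Hz frames)
        L = self.build_states([(12, 30), (48, 60), (78, 85)], 95, "left")
        R = self.build_states([(3, 20), (39, 50), (69, 76)], 95, "right")
        xyz_l = np.outer(np.arange(95), [0.02, 0, 0])
        xyz_r = np.outer(np.arange(95), [0.02, 0, 0]) + [0.3, 0, 0]
        sk = skeleton_with_ankles(xyz_l, xyz_r)
        records = ge.compute_parameters(L, R, sk)
        left = [r for r in records if r.foot == "left"]
        assert left[0].heel_strike_time == pytest.approx(2.0)
        assert left[0].stance_time == pytest.approx(0.6, abs=1e-9)
        assert left[0].swing_time == pytest.approx(0.4, abs=1e-9)

    def test_never_interleaving_feet_rejected(self):
        L = self.build_states([(5, 10), (15, 20), (25, 30)], 40, "left")
        R = self.build_states([], 40, "right")
        sk = skeleton_with_ankles(np.zeros((40, 3)), np.zeros((40, 3)))
        with pytest.raises(ValueError, match="interleave"):
            ge.compute_parameters(L, R, sk)

    def test_stance_plus_swing_equals_stride(self, walk_gt):
        from stereogait.pipeline_cli import skeleton_from_table, _detect_steps, PipelineSettings
        from stereogait.sync_align import resample_series
        from stereogait.synthetic_gait import render_reference
        from conftest import NOISE_FREE_SCENE

        ref = render_reference(walk_gt, NOISE_FREE_SCENE)
        sk = skeleton_from_table(resample_series(ref, 30.0))
        _, states, steps = _detect_steps(sk, PipelineSettings())
        assert len(steps) >= 3
        stride = walk_gt.gait.stride_time
        for rec in steps:
            assert rec.stance_time + rec.swing_time == pytest.approx(
                stride, abs=1.0 / 30.0 + 1e-9
            )

    def test_step_length_recovered_on_noise_free_walk(self, walk_gt):
        from stereogait.pipeline_cli import skeleton_from_table, _detect_steps, PipelineSettings
        from stereogait.sync_align import resample_series
        from stereogait.synthetic_gait import render_reference
        from conftest import NOISE_FREE_SCENE

        ref = render_reference(walk_gt, NOISE_FREE_SCENE)
        sk = skeleton_from_table(resample_series(ref, 30.0))
        _, _, steps = _detect_steps(sk, PipelineSettings())
        lengths = [s.step_length for s in steps if s.step_length is not None]
        assert len(lengths) >= 2
        assert abs(np.mean(lengths) - walk_gt.gait.step_length) <= 0.01

    def test_both_systems_agree_on_times_within_one_frame(
        self, noise_free_recording, walk_gt
    ):
        """The detection bias is shared: markerless vs reference times match."""
        from stereogait.pipeline_cli import run_recording

        a, b, rig, ref = noise_free_recording
        res = run_recording(a, b, rig, ref)
        assert res.param_report.rms.get("stance_time_s", 1.0) <= 1.0 / 30.0 + 1e-9
        assert res.param_report.rms.get("swing_time_s", 1.0) <= 1.0 / 30.0 + 1e-9


class TestGapInterpolation:
    def test_short_gap_filled_linearly(self):
        pos = np.outer(np.arange(30), [0.1, 0.0, 0.0])
        valid = np.ones((30, 18), bool)
        valid[10:14, COCO18_INDEX["LAnkle"]] = False
        sk = skeleton_with_ankles(pos, np.zeros((30, 3)), valid=valid)
        out = ge.interpolate_short_gaps(sk, max_gap=5)
        j = COCO18_INDEX["LAnkle"]
        assert out.valid[10:14, j].all()
        assert np.allclose(out.xyz[10:14, j, 0], [1.0, 1.1, 1.2, 1.3], atol=1e-12)

    def test_long_gap_left_invalid(self):
        pos = np.outer(np.arange(30), [0.1, 0.0, 0.0])
        valid = np.ones((30, 18), bool)
        valid[10:18, COCO18_INDEX["LAnkle"]] = False
        sk = skeleton_with_ankles(pos, np.zeros((30, 3)), valid=valid)
        out = ge.interpolate_short_gaps(sk, max_gap=5)
        assert not out.valid[10:18, COCO18_INDEX["LAnkle"]].any()

    def test_leading_gap_not_extrapolated(self):
        pos = np.outer(np.arange(30), [0.1, 0.0, 0.0])
        valid = np.ones((30, 18), bool)
        valid[:3, COCO18_INDEX["LAnkle"]] = False
        sk = skeleton_with_ankles(pos, np.zeros((30, 3)), valid=valid)
        out = ge.interpolate_short_gaps(sk, max_gap=5)
        assert not out.valid[:3, COCO18_INDEX["LAnkle"]].any()
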