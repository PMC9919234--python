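"""Tests of motion/turn detection, distances, speeds and smoothing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitfuse import (
    BinaryIndicator,
    MotionDetectionConfig,
    ScenarioConfig,
    TurnDetectionConfig,
    build_reference_trajectory,
    detect_motion,
    detect_turns,
    mean_walking_speed,
    morphological_close,
    smooth_track,
    summarize_gait,
    travelled_distance,
)


def walk(waypoints, v, rate=10.0):
    scen = ScenarioConfig(waypoints=waypoints, walking_speed=v)
    traj = build_reference_trajectory(scen, rate)
    return traj.t, traj.xy


def brute_close(values, length):
    """Independent dilate-then-erode on an infinite zero background."""
    v = np.concatenate([np.zeros(length, bool), values.astype(bool), np.zeros(length, bool)])
    n = v.size
    offsets = range(-(length // 2), length - length // 2)  # origin-centred element
    dil = np.zeros(n, bool)
    for i in range(n):
        dil[i] = any(0 <= i - o < n and v[i - o] for o in offsets)
    ero = np.zeros(n, bool)
    for i in range(n):
        ero[i] = all(dil[i + o] if 0 <= i + o < n else False for o in offsets)
    return ero[length:-length]


class TestMotionDetection:
    def test_stationary_track_never_moves(self):
        t = np.arange(50) / 10
        xy = np.tile([2.0, 3.0], (50, 1))
        ind = detect_motion(t, xy)
        assert not ind.values.any()

    def test_straight_walk_matches_hand_evaluated_rule(self):
        t, xy = walk([(0, 0), (5, 0)], 0.5)
        cfg = MotionDetectionConfig(T_m=0.45, D=0.1)
        ind = detect_motion(t, xy, cfg)
        # independent per-sample evaluation of the windowed displacement rule
        for n in range(len(t)):
            if n == 0:
                expect = False
            else:
                n0 = min(
                    (v for v in range(0, n) if t[v] >= t[n] - cfg.T_m), default=n - 1
                )
                d = math.hypot(xy[n, 0] - xy[n0, 0], xy[n, 1] - xy[n0, 1])
                expect = d > (t[n] - t[n0]) / cfg.T_m * cfg.D
            assert bool(ind.values[n]) == expect

    def test_walk_pause_walk_time_in_motion(self):
        # scripted: 5 s walking, 4 s standing, 5 s walking at 10 Hz
        t = np.arange(141) / 10
        x = np.concatenate([
            0.5 * t[:50],
            np.full(40, 0.5 * t[49]),
            0.5 * t[49] + 0.5 * (t[90:] - t[90]),
        ])
        xy = np.column_stack([x, np.zeros_like(x)])
        g = summarize_gait(t, xy)
        assert g.time_in_motion == pytest.approx(10.1, abs=0.45)

    def test_nonmonotone_timestamps_rejected(self):
        with pytest.raises(ValueError):
            detect_motion([0.0, 0.2, 0.1], np.zeros((3, 2)))


class TestMorphologicalClosing:
    def test_all_ones_preserved(self):
        ind = BinaryIndicator(np.arange(30) / 10, np.ones(30), "motion")
        closed = morphological_close(ind, 0.45)
        assert closed.values.all() and closed.closed

    def test_short_gap_filled(self):
        v = np.ones(30)
        v[10:12] = 0  # gap of 2 < element length 5 (0.45 s at 10 Hz)
        ind = BinaryIndicator(np.arange(30) / 10, v, "motion")
        assert morphological_close(ind, 0.45).values.all()

    def test_matches_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(1)
        t = np.arange(40) / 10
        for _ in range(200):
            v = rng.integers(0, 2, size=40)
            got = morphological_close(BinaryIndicator(t, v, "motion"), 0.45).values
            expect = brute_close(v, 5)
            np.testing.assert_array_equal(got.astype(bool), expect)

    @given(data=st.lists(st.integers(0, 1), min_size=5, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_closing_laws(self, data):
        v = np.asarray(data)
        ind = BinaryIndicator(np.arange(v.size) / 10.0, v, "motion")
        once = morphological_close(ind, 0.5)
        twice = morphological_close(once, 0.5)
        assert np.all(once.values >= v)  # extensive
        np.testing.assert_array_equal(once.values, twice.values)  # idempotent


class TestTurnDetection:
    def test_straight_walk_has_no_turns(self):
        t, xy = walk([(0, 0), (8, 0)], 1.0)
        _, n = detect_turns(t, xy)
        assert n == 0

    def test_single_right_angle_is_one_turn(self):
        t, xy = walk([(0, 0), (3, 0), (3, 3)], 0.7)
        _, n = detect_turns(t, xy, TurnDetectionConfig(T_t=1.0, Phi=math.radians(60)))
        assert n == 1

    def test_rectangle_lap_has_four_turns(self):
        t, xy = walk([(0, 0), (4, 0), (4, 3), (0, 3), (0, 0), (2, 0)], 0.7)
        _, n = detect_turns(t, xy, TurnDetectionConfig(T_t=1.0, Phi=math.radians(60)))
        assert n == 4

    def test_shallow_bend_below_threshold_not_counted(self):
        t, xy = walk([(0, 0), (3, 0), (6, 1.5)], 0.7)  # ~27 degree bend
        _, n = detect_turns(t, xy)
        assert n == 0

    @given(angle=st.floats(0, 2 * math.pi))
    @settings(max_examples=25, deadline=None)
    def test_rotation_invariance(self, angle):
        t, xy = walk([(0, 0), (3, 0), (3, 3), (0, 3)], 0.7)
        rot = np.array([[math.cos(angle), -math.sin(angle)],
                        [math.sin(angle), math.cos(angle)]])
        _, n_base = detect_turns(t, xy)
        _, n_rot = detect_turns(t, xy @ rot.T)
        assert n_base == n_rot

    def test_pause_inside_walk_does_not_create_turns(self):
        t = np.arange(100) / 10
        x = np.minimum(0.7 * t, 3.5)  # walk then stand still
        xy = np.column_stack([x, np.zeros_like(x)])
        _, n = detect_turns(t, xy)
        assert n == 0


class TestDistanceAndSpeed:
    def test_three_four_five_triangle(self):
        assert travelled_distance([(0, 0), (3, 4)]) == pytest.approx(5.0)

    def test_constant_position_zero(self):
        assert travelled_distance([(1, 1), (1, 1), (1, 1)]) == 0.0

    def test_random_polyline_matches_cumulative_norm_oracle(self):
        rng = np.random.default_rng(3)
        xy = rng.normal(size=(100, 2))
        oracle = sum(
            math.hypot(xy[i + 1, 0] - xy[i, 0], xy[i + 1, 1] - xy[i, 1])
            for i in range(99)
        )
        assert travelled_distance(xy) == pytest.approx(oracle, abs=1e-9)

    @given(angle=st.floats(0, 2 * math.pi), dx=st.floats(-5, 5), dy=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_rigid_motion_invariance(self, angle, dx, dy):
        rng = np.random.default_rng(8)
        xy = rng.normal(size=(30, 2))
        rot = np.array([[math.cos(angle), -math.sin(angle)],
                        [math.sin(angle), math.cos(angle)]])
        moved = xy @ rot.T + [dx, dy]
        assert travelled_distance(moved) == pytest.approx(travelled_distance(xy), rel=1e-9)

    @pytest.mark.parametrize("v", [0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
    def test_mean_speed_recovers_scripted_speed(self, v):
        t, xy = walk([(0, 0), (10, 0)], v)
        g = summarize_gait(t, xy)
        assert g.mean_speed == pytest.approx(v, rel=0.02)

    def test_stationary_track_has_undefined_speed(self):
        t = np.arange(30) / 10
        xy = np.tile([1.0, 1.0], (30, 1))
        g = summarize_gait(t, xy)
        assert math.isnan(g.mean_speed)

    def test_mismatched_indicator_rejected(self):
        t = np.arange(30) / 10
        xy = np.zeros((30, 2))
        ind = BinaryIndicator(np.arange(10) / 10, np.ones(10), "motion")
        with pytest.raises(ValueError):
            mean_walking_speed(t, xy, ind)


class TestSmoothing:
    def test_constant_track_unchanged(self):
        t = np.arange(50) / 10
        xy = np.tile([2.0, -1.0], (50, 1))
        _, sm = smooth_track(t, xy, 0.5)
        np.testing.assert_allclose(sm, xy, atol=1e-12)

    def test_single_sample_window_is_identity(self):
        t = np.arange(50) / 10
        xy = np.random.default_rng(0).normal(size=(50, 2))
        _, sm = smooth_track(t, xy, 0.05)
        np.testing.assert_array_equal(sm, xy)

    def test_linear_ramp_interior_unchanged(self):
        t = np.arange(50) / 10
        xy = np.column_stack([0.3 * t, -0.1 * t])
        _, sm = smooth_track(t, xy, 0.5)
        np.testing.assert_allclose(sm[5:-5], xy[5:-5], atol=1e-10)

    def test_smoothing_never_lengthens_a_cornered_path(self):
        t, xy = walk([(0, 0), (3, 0), (3, 3), (0, 3)], 0.7)
        _, sm = smooth_track(t, xy, 0.7)
        assert travelled_distance(sm) <= travelled_distance(xy) + 1e-12
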