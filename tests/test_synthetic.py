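"""Tests of the trajectory/sensor simulator."""

import numpy as np
import pytest

from gaitfuse import (
    DepthModelConfig,
    RadarNoiseConfig,
    ScenarioConfig,
    Trajectory,
    build_reference_trajectory,
    generate_training_set,
    simulate_depth_track,
    simulate_radar_track,
)
from gaitfuse.synthetic import segment_blocked


def scenario(waypoints, v, **kw):
    kw.setdefault("depth_sensor_position", (2.5, -1.0))
    return ScenarioConfig(waypoints=waypoints, walking_speed=v, **kw)


class TestReferenceTrajectory:
    def test_straight_segment_sampling(self):
        traj = build_reference_trajectory(scenario([(0, 0), (1, 0)], 0.5), rate=10)
        assert len(traj) == 21
        assert traj.t[-1] == pytest.approx(2.0)
        np.testing.assert_allclose(traj.xy[-1], [1, 0], atol=1e-12)
        steps = np.diff(traj.xy[:, 0])
        np.testing.assert_allclose(steps, 0.05, atol=1e-12)

    def test_total_duration_is_path_length_over_speed(self):
        traj = build_reference_trajectory(scenario([(0, 0), (0, 3), (4, 3)], 1.0), rate=10)
        assert traj.t[-1] == pytest.approx(7.0)

    def test_rectangle_lap_duration_matches_bruteforce_length(self):
        wp = [(0, 0), (4, 0), (4, 3), (0, 3), (0, 0)]
        # independent oracle: accumulate segment lengths one by one
        length = sum(
            ((x2 - x1) ** 2 + (y2 - y1) ** 2) ** 0.5
            for (x1, y1), (x2, y2) in zip(wp[:-1], wp[1:])
        )
        traj = build_reference_trajectory(scenario(wp, 0.7), rate=10)
        assert length / 0.7 == pytest.approx(20.0)
        assert traj.t[-1] == pytest.approx(np.floor(20.0 * 10) / 10)

    def test_constant_segment_speed(self):
        # chord speed equals the walking speed except where a step cuts a
        # corner of the polyline (the chord is shorter than the arc there)
        traj = build_reference_trajectory(scenario([(0, 0), (2, 1), (1, 3)], 0.8), rate=10)
        d = np.diff(traj.xy, axis=0)
        speeds = np.hypot(d[:, 0], d[:, 1]) / np.diff(traj.t)
        assert np.all(speeds <= 0.8 + 1e-9)
        assert np.mean(np.abs(speeds - 0.8) < 1e-9) > 0.9

    def test_coincident_waypoints_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            build_reference_trajectory(scenario([(0, 0), (0, 0), (1, 0)], 0.5), rate=10)

    @pytest.mark.parametrize("rate", [7.0, 10.0, 30.0])
    @pytest.mark.parametrize("v", [0.5, 0.73, 1.0])
    def test_sample_count_contract(self, rate, v):
        traj = build_reference_trajectory(scenario([(0, 0), (3.3, 1.1)], v), rate)
        duration = np.hypot(3.3, 1.1) / v
        assert len(traj) == int(np.floor(duration * rate + 1e-9)) + 1


class TestRadarTrack:
    def straight(self, n=200, rate=10.0, v=0.5):
        t = np.arange(n) / rate
        return Trajectory(t=t, xy=np.column_stack([v * t, np.zeros(n)]), walking_speed=v)

    def test_zero_noise_is_identity(self):
        traj = self.straight()
        track = simulate_radar_track(traj, RadarNoiseConfig(noise_std=0.0), seed=3)
        np.testing.assert_array_equal(track.xy, traj.xy)
        np.testing.assert_array_equal(track.t, traj.t)

    def test_white_noise_sample_std(self):
        traj = self.straight(n=10_000)
        cfg = RadarNoiseConfig(noise_std=0.2, red_noise_coefficient=0.0, smoothing_window=1)
        track = simulate_radar_track(traj, cfg, seed=7)
        resid = track.xy - traj.xy
        assert np.std(resid) == pytest.approx(0.2, rel=0.05)

    def test_red_noise_lag1_autocorrelation(self):
        traj = self.straight(n=10_000)
        cfg = RadarNoiseConfig(noise_std=0.1, red_noise_coefficient=0.95, smoothing_window=1)
        track = simulate_radar_track(traj, cfg, seed=11)
        e = (track.xy - traj.xy)[:, 0]
        rho = np.corrcoef(e[:-1], e[1:])[0, 1]
        assert rho == pytest.approx(0.95, abs=0.03)

    def test_deterministic_under_seed(self):
        traj = self.straight()
        a = simulate_radar_track(traj, RadarNoiseConfig(), seed=5)
        b = simulate_radar_track(traj, RadarNoiseConfig(), seed=5)
        np.testing.assert_array_equal(a.xy, b.xy)

    def test_smoothing_reduces_dispersion(self):
        traj = self.straight(n=5000)
        base = dict(noise_std=0.1, red_noise_coefficient=0.5)
        raw = simulate_radar_track(traj, RadarNoiseConfig(smoothing_window=1, **base), seed=2)
        sm = simulate_radar_track(traj, RadarNoiseConfig(smoothing_window=11, **base), seed=2)
        assert np.std(sm.xy - traj.xy) < np.std(raw.xy - traj.xy)


class TestDepthTrack:
    def test_degenerate_model_reproduces_trajectory(self):
        scen = scenario([(0, 2), (4, 2)], 0.5, depth_rate=10.0)
        traj = build_reference_trajectory(scen, 10.0)
        cfg = DepthModelConfig(
            ellipse_semi_axes=(0.0, 0.0), sine_amplitude=0.0, sine_phase=0.0
        )
        track = simulate_depth_track(traj, cfg, scen, fragment=False, seed=0)
        np.testing.assert_allclose(track.xy, traj.xy, atol=1e-9)

    def test_total_occlusion_gives_empty_track(self):
        scen = scenario(
            [(0, 2), (4, 2)], 0.5,
            obstacle_regions=[(-1.0, 0.0, 5.0, 1.5)],  # wall between sensor and path
        )
        traj = build_reference_trajectory(scen, 10.0)
        track = simulate_depth_track(traj, DepthModelConfig(), scen, fragment=True, seed=0)
        assert len(track) == 0

    def test_visible_side_bias_matches_boundary_search(self):
        # person walking east, due north of the sensor: the reported point is
        # the ellipse boundary point nearest the sensor, found by brute force
        scen = scenario([(2.5, 2.0), (3.5, 2.0)], 0.5)
        traj = build_reference_trajectory(scen, 10.0)
        cfg = DepthModelConfig(
            ellipse_semi_axes=(0.25, 0.15), sine_amplitude=0.0, sine_phase=0.0
        )
        track = simulate_depth_track(traj, cfg, scen, fragment=False, seed=0)
        i = 0  # first sample: centre (2.5, 2.0) due north of sensor (2.5, -1.0)
        theta = np.linspace(0, 2 * np.pi, 200_001)
        boundary = np.column_stack(
            [2.5 + 0.25 * np.cos(theta), 2.0 + 0.15 * np.sin(theta)]
        )
        sensor = np.array([2.5, -1.0])
        nearest = boundary[np.argmin(np.hypot(*(boundary - sensor).T))]
        np.testing.assert_allclose(track.xy[i], nearest, atol=1e-6)
        # displaced toward the sensor by the across-path semi-axis
        np.testing.assert_allclose(track.xy[i], [2.5, 2.0 - 0.15], atol=1e-6)

    def test_person_on_sensor_rejected(self):
        scen = scenario([(2.5, -1.0), (3.5, 2.0)], 0.5)
        traj = build_reference_trajectory(scen, 10.0)
        cfg = DepthModelConfig(sine_amplitude=0.0, sine_phase=0.0)
        with pytest.raises(ValueError, match="sensor"):
            simulate_depth_track(traj, cfg, scen, fragment=False, seed=0)

    @staticmethod
    def _segment_hits_rect(p, q, rect):
        """Exact slab-clipping oracle for segment/rectangle intersection."""
        x0, y0, x1, y1 = rect
        tmin, tmax = 0.0, 1.0
        for a, b, lo, hi in ((p[0], q[0], x0, x1), (p[1], q[1], y0, y1)):
            d = b - a
            if d == 0:
                if a < lo or a > hi:
                    return False
                continue
            t1, t2 = (lo - a) / d, (hi - a) / d
            if t1 > t2:
                t1, t2 = t2, t1
            tmin, tmax = max(tmin, t1), min(tmax, t2)
            if tmin > tmax:
                return False
        return True

    def test_occlusion_matches_bruteforce_intersection(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            sensor = rng.uniform(-2, 6, size=2)
            points = rng.uniform(-2, 6, size=(40, 2))
            rects = []
            for _ in range(2):
                xs = np.sort(rng.uniform(-2, 6, size=2))
                ys = np.sort(rng.uniform(-2, 6, size=2))
                rects.append((xs[0], ys[0], xs[1], ys[1]))
            got = segment_blocked(sensor, points, rects)
            for j, p in enumerate(points):
                hit = any(self._segment_hits_rect(sensor, p, r) for r in rects)
                assert got[j] == hit


class TestTrainingSet:
    def small_scenarios(self):
        return [
            scenario([(0, 0), (3, 0)], 0.7),
            scenario([(0, 0), (0, 3)], 0.7),
        ]

    def test_counts_and_fragmentation(self):
        ds = generate_training_set(
            self.small_scenarios(), n_per_traj=4, fragment_fraction=0.5, seed=0
        )
        assert len(ds) == 8
        full = int(np.floor((3 / 0.7) * 10 + 1e-9)) + 1
        n_frag = sum(len(w.depth) < full for w in ds)
        assert n_frag == 4  # round(0.5 * 4) per trajectory, 2 trajectories

    def test_training_rates_are_10hz(self):
        ds = generate_training_set(self.small_scenarios(), n_per_traj=1,
                                   fragment_fraction=0.0, seed=0)
        for w in ds:
            np.testing.assert_allclose(np.diff(w.radar.t), 0.1, atol=1e-12)
            np.testing.assert_allclose(np.diff(w.depth.t), 0.1, atol=1e-12)

    def test_fragment_zero_leaves_no_gaps(self):
        ds = generate_training_set(self.small_scenarios(), n_per_traj=1,
                                   fragment_fraction=0.0, seed=3)
        for w in ds:
            assert len(w.depth) == len(w.trajectory)

    def test_same_seed_bit_identical(self):
        a = generate_training_set(self.small_scenarios(), 2, 0.5, seed=9)
        b = generate_training_set(self.small_scenarios(), 2, 0.5, seed=9)
        for wa, wb in zip(a, b):
            np.testing.assert_array_equal(wa.radar.xy, wb.radar.xy)
            np.testing.assert_array_equal(wa.depth.xy, wb.depth.xy)
            np.testing.assert_array_equal(wa.depth.t, wb.depth.t)
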