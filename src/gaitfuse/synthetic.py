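"""Synthetic reference trajectories and radar/depth measurement tracks.

The simulator emulates the measurement chain of an indoor monitoring system
with two position sensors observing a walking person:

* **Impulse radar** — reports 2-D positions at 10 Hz.  Measurement error is
  modelled as zero-mean *red* (strongly autocorrelated AR(1)) noise passed
  through a centred moving-average filter, mimicking the smoothing applied
  in radar track preprocessing.
* **Depth camera** — reports positions at 10 Hz (training) or 30 Hz
  (evaluation).  The person's silhouette is modelled as an ellipse whose
  centre follows the reference path displaced laterally by a sine wave in
  arclength; the reported position is the boundary point of the ellipse
  facing the sensor, which biases the track toward the sensor — depth
  cameras see only the near side of the body.  Occlusion by obstacles
  removes samples whose sensor line of sight crosses an obstacle rectangle.

Reference trajectories are constant-speed traversals of a waypoint
polyline; the walking speed is a scenario parameter (a metronome-paced
walk), so segment speed is constant by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely

from .tracks import SensorTrack, Trajectory

__all__ = [
    "ScenarioConfig",
    "RadarNoiseConfig",
    "DepthModelConfig",
    "WalkRealisation",
    "build_reference_trajectory",
    "simulate_radar_track",
    "simulate_depth_track",
    "generate_training_set",
    "simulate_walk",
    "segment_blocked",
    "smoothed_red_noise_std",
]


@dataclass
class ScenarioConfig:
    """Geometry and acquisition parameters of one movement scenario."""

    waypoints: list
    walking_speed: float
    radar_rate: float = 10.0
    depth_rate: float = 10.0
    n_realisations: int = 1
    obstacle_regions: list = field(default_factory=list)  # (xmin, ymin, xmax, ymax)
    depth_sensor_position: tuple = (2.5, -1.0)
    seed: int = 0
    name: str = "scenario"

    def __post_init__(self) -> None:
        if self.walking_speed <= 0:
            raise ValueError("walking_speed must be positive")
        if self.radar_rate <= 0 or self.depth_rate <= 0:
            raise ValueError("sensor rates must be positive")
        if self.n_realisations < 1:
            raise ValueError("n_realisations must be at least 1")


@dataclass
class RadarNoiseConfig:
    """Red-noise model of the radar measurement error.

    ``noise_std`` is the *stationary* standard deviation of the AR(1)
    process before smoothing; ``red_noise_coefficient`` is its lag-1
    autoregression coefficient (0 gives white noise); ``smoothing_window``
    is the length, in samples, of the centred moving average applied to the
    noise (shrinking at the edges).
    """

    noise_std: float = 0.10
    red_noise_coefficient: float = 0.95
    smoothing_window: int = 11
    reported_std: float | None = None  # per-sample sigma written to the track

    def __post_init__(self) -> None:
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")
        if not 0 <= self.red_noise_coefficient < 1:
            raise ValueError("red_noise_coefficient must be in [0, 1)")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be at least 1")


@dataclass
class DepthModelConfig:
    """Silhouette model behind the depth-sensor track.

    The ellipse has its major semi-axis ``a`` along the walking direction
    and minor semi-axis ``b`` across it.  The centre oscillates around the
    reference path with the given amplitude and arclength period (gait
    sway); a random phase per realisation makes realisations distinct.
    """

    ellipse_semi_axes: tuple = (0.25, 0.15)
    sine_amplitude: float = 0.05
    sine_period: float = 1.2
    fragment_fraction: float = 0.5
    sine_phase: float | None = None  # None -> drawn uniformly per realisation
    reported_std: float = 0.10

    def __post_init__(self) -> None:
        a, b = self.ellipse_semi_axes
        if a < 0 or b < 0:
            raise ValueError("ellipse semi-axes must be non-negative")
        if not 0 <= self.fragment_fraction <= 1:
            raise ValueError("fragment_fraction must be in [0, 1]")
        if self.sine_period <= 0:
            raise ValueError("sine_period must be positive")


@dataclass
class WalkRealisation:
    """One simulated walk: the reference path plus both sensor tracks."""

    trajectory: Trajectory
    radar: SensorTrack
    depth: SensorTrack


def build_reference_trajectory(config: ScenarioConfig, rate: float) -> Trajectory:
    """Sample the waypoint polyline at constant walking speed.

    Emits positions every ``1/rate`` seconds; the number of samples is
    ``floor(duration * rate) + 1`` where duration = path length / speed.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    wp = np.asarray(config.waypoints, dtype=float)
    if wp.ndim != 2 or wp.shape[1] != 2 or wp.shape[0] < 2:
        raise ValueError("at least two (x, y) waypoints are required")
    seg = np.diff(wp, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(seg_len == 0):
        raise ValueError(
            "coincident consecutive waypoints: the path direction is undefined there"
        )
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    duration = cum[-1] / config.walking_speed
    n = int(math.floor(duration * rate + 1e-9)) + 1
    t = np.arange(n) / rate
    s = config.walking_speed * t
    x = np.interp(s, cum, wp[:, 0])
    y = np.interp(s, cum, wp[:, 1])
    return Trajectory(t=t, xy=np.column_stack([x, y]), walking_speed=config.walking_speed)


def _ar1(rng: np.random.Generator, n: int, coeff: float, std: float) -> np.ndarray:
    """Stationary zero-mean AR(1) sequence with the given marginal std."""
    if std == 0 or n == 0:
        return np.zeros(n)
    innov_std = std * math.sqrt(1.0 - coeff**2)
    w = rng.normal(0.0, 1.0, size=n)
    e = np.empty(n)
    e[0] = std * w[0]
    for i in range(1, n):
        e[i] = coeff * e[i - 1] + innov_std * w[i]
    return e


def _moving_average(v: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    if window <= 1 or v.size == 0:
        return v.copy()
    half = (window - 1) // 2
    c = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(v.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, v.size - 1)
    return (c[hi + 1] - c[lo]) / (hi - lo + 1)


def smoothed_red_noise_std(cfg: RadarNoiseConfig) -> float:
    """Stationary std of the AR(1) noise after the moving-average filter.

    For a window of W samples and AR coefficient a, the variance of the mean
    of W consecutive samples is sigma^2/W^2 * (W + 2*sum_{k=1}^{W-1}(W-k) a^k).
    """
    w = cfg.smoothing_window
    a = cfg.red_noise_coefficient
    k = np.arange(1, w)
    factor = (w + 2.0 * np.sum((w - k) * a**k)) / w**2
    return cfg.noise_std * math.sqrt(factor)


def simulate_radar_track(
    traj: Trajectory, cfg: RadarNoiseConfig, seed: int | np.random.Generator = 0
) -> SensorTrack:
    """Corrupt the reference with smoothed red noise, per coordinate.

    The AR(1) noise is generated independently per coordinate and smoothed
    with the centred moving average before being added to the reference, so
    a zero-noise configuration reproduces the trajectory exactly.
    """
    if len(traj) == 0:
        raise ValueError("trajectory must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(traj)
    noise = np.column_stack(
        [
            _moving_average(
                _ar1(rng, n, cfg.red_noise_coefficient, cfg.noise_std),
                cfg.smoothing_window,
            )
            for _ in range(2)
        ]
    )
    sigma = cfg.reported_std if cfg.reported_std is not None else smoothed_red_noise_std(cfg)
    cov = np.broadcast_to(np.eye(2) * sigma**2, (n, 2, 2)).copy()
    return SensorTrack(sensor_id="radar", t=traj.t.copy(), xy=traj.xy + noise, cov=cov)


def segment_blocked(p0, points, rects) -> np.ndarray:
    """Which sight lines from ``p0`` to each point cross an obstacle rectangle."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    blocked = np.zeros(points.shape[0], dtype=bool)
    if not len(rects):
        return blocked
    p0 = np.asarray(p0, dtype=float)
    coords = np.stack([np.broadcast_to(p0, points.shape), points], axis=1)
    lines = shapely.linestrings(coords)
    for xmin, ymin, xmax, ymax in rects:
        blocked |= shapely.intersects(lines, shapely.box(xmin, ymin, xmax, ymax))
    return blocked


def _headings(xy: np.ndarray) -> np.ndarray:
    """Unit walking-direction vector at each sample (central differences)."""
    if xy.shape[0] == 1:
        return np.array([[1.0, 0.0]])
    d = np.gradient(xy, axis=0)
    norm = np.hypot(d[:, 0], d[:, 1])
    norm[norm == 0] = 1.0
    return d / norm[:, None]


def simulate_depth_track(
    traj: Trajectory,
    cfg: DepthModelConfig,
    scenario: ScenarioConfig,
    fragment: bool = False,
    seed: int | np.random.Generator = 0,
) -> SensorTrack:
    """Depth-camera view of the walking person.

    The silhouette ellipse follows the reference path displaced laterally by
    ``sine_amplitude * sin(2*pi*arclength/sine_period + phase)``; the sensor
    reports the ellipse boundary point on the line from the sensor to the
    ellipse centre (visible-side bias).  With ``fragment`` set, samples whose
    line of sight from the sensor crosses an obstacle rectangle are removed.
    """
    if len(traj) == 0:
        raise ValueError("trajectory must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # resample the reference at the depth-sensor rate
    rate = scenario.depth_rate
    duration = traj.t[-1] - traj.t[0]
    n = int(math.floor(duration * rate + 1e-9)) + 1
    t = traj.t[0] + np.arange(n) / rate
    centre = traj.position_at(t)

    # arclength-parameterised lateral sway
    step = np.vstack([[0.0, 0.0], np.diff(centre, axis=0)])
    s = np.cumsum(np.hypot(step[:, 0], step[:, 1]))
    u = _headings(centre)  # along-path unit vector
    nvec = np.column_stack([-u[:, 1], u[:, 0]])  # left normal
    phase = cfg.sine_phase
    if phase is None:
        phase = rng.uniform(0.0, 2.0 * math.pi)
    sway = cfg.sine_amplitude * np.sin(2.0 * math.pi * s / cfg.sine_period + phase)
    centre = centre + sway[:, None] * nvec

    sensor = np.asarray(scenario.depth_sensor_position, dtype=float)
    d = sensor - centre
    dist = np.hypot(d[:, 0], d[:, 1])
    if np.any(dist == 0):
        raise ValueError("person position coincides with the depth sensor position")
    d /= dist[:, None]
    a, b = cfg.ellipse_semi_axes
    if a == 0 or b == 0:
        reported = centre
    else:
        # radius of the ellipse (axes along u, n) in the sensor direction
        du = np.sum(d * u, axis=1)
        dn = np.sum(d * nvec, axis=1)
        r = 1.0 / np.sqrt((du / a) ** 2 + (dn / b) ** 2)
        reported = centre + r[:, None] * d

    keep = np.ones(n, dtype=bool)
    if fragment and scenario.obstacle_regions:
        keep = ~segment_blocked(sensor, centre, scenario.obstacle_regions)
    sigma = cfg.reported_std
    cov = np.broadcast_to(np.eye(2) * sigma**2, (int(keep.sum()), 2, 2)).copy()
    return SensorTrack(sensor_id="depth", t=t[keep], xy=reported[keep], cov=cov)


def _random_gaps(
    track: SensorTrack, rng: np.random.Generator, n_gaps=(1, 3), gap_seconds=(1.0, 5.0)
) -> SensorTrack:
    """Remove random contiguous segments — occlusion for scenarios without
    explicit obstacle geometry.  Gap durations of a few seconds mimic a
    person disappearing behind a room-scale obstacle."""
    n = len(track)
    if n == 0:
        return track
    keep = np.ones(n, dtype=bool)
    rate = 1.0 / np.median(np.diff(track.t)) if n > 1 else 1.0
    for _ in range(rng.integers(n_gaps[0], n_gaps[1] + 1)):
        width = max(1, int(round(rng.uniform(*gap_seconds) * rate)))
        start = rng.integers(0, max(1, n - width))
        keep[start : start + width] = False
    return SensorTrack(
        sensor_id=track.sensor_id, t=track.t[keep], xy=track.xy[keep], cov=track.cov[keep]
    )


def simulate_walk(
    scenario: ScenarioConfig,
    radar_cfg: RadarNoiseConfig,
    depth_cfg: DepthModelConfig,
    fragment: bool,
    seed: int | np.random.Generator,
    gap_mode: str = "obstacles",
) -> WalkRealisation:
    """Simulate one walk: reference at the radar rate plus both sensor tracks."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref = build_reference_trajectory(scenario, scenario.radar_rate)
    radar = simulate_radar_track(ref, radar_cfg, rng)
    if gap_mode == "random":
        depth = simulate_depth_track(ref, depth_cfg, scenario, fragment=False, seed=rng)
        if fragment:
            depth = _random_gaps(depth, rng)
    else:
        depth = simulate_depth_track(ref, depth_cfg, scenario, fragment=fragment, seed=rng)
    return WalkRealisation(trajectory=ref, radar=radar, depth=depth)


def generate_training_set(
    trajectories: list[ScenarioConfig],
    n_per_traj: int = 40,
    fragment_fraction: float = 0.5,
    seed: int = 0,
    radar_cfg: RadarNoiseConfig | None = None,
    depth_cfg: DepthModelConfig | None = None,
    gap_mode: str = "random",
) -> list[WalkRealisation]:
    """Generate the paired training realisations for the neural fusers.

    Both sensors are sampled at 10 Hz; per trajectory, exactly
    ``round(fragment_fraction * n_per_traj)`` of the depth realisations are
    fragmented.  Per-realisation RNGs are spawned from the master seed via
    ``numpy.random.SeedSequence`` (child i*n_per_traj + j for trajectory i,
    realisation j), so any subset of walks is independently reproducible.
    """
    if n_per_traj < 1:
        raise ValueError("n_per_traj must be at least 1")
    radar_cfg = radar_cfg or RadarNoiseConfig()
    depth_cfg = depth_cfg or DepthModelConfig(fragment_fraction=fragment_fraction)
    n_frag = int(round(fragment_fraction * n_per_traj))
    children = np.random.SeedSequence(seed).spawn(len(trajectories) * n_per_traj)
    out: list[WalkRealisation] = []
    for i, scen in enumerate(trajectories):
        scen10 = replace(scen, radar_rate=10.0, depth_rate=10.0)
        for j in range(n_per_traj):
            rng = np.random.default_rng(children[i * n_per_traj + j])
            out.append(
                simulate_walk(
                    scen10, radar_cfg, depth_cfg, fragment=j < n_frag, seed=rng,
                    gap_mode=gap_mode,
                )
            )
    return out
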