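"""Kalman-filter fusion of asynchronous radar and depth observations.

The motion model is the nearly-constant-velocity (white-acceleration) model:
the state x = [x, vx, y, vy] evolves as x_n = F_n x_{n-1} + G_n alpha_n with
a zero-mean Gaussian random acceleration alpha of per-axis std sigma_alpha.
Observations are positions, z = H x + eta, with a known per-sample noise
covariance.  Because the two sensors sample asynchronously, each incoming
observation — radar or depth — triggers one predict/update cycle, and the
posterior at every observation time is the fused estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tracks import FusedTrack, SensorTrack

__all__ = [
    "KFModelParams",
    "KFState",
    "Observation",
    "KFStepDiagnostics",
    "kf_predict",
    "kf_update",
    "kf_fuse_tracks",
]

H = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 0.0, 1.0, 0.0]])


@dataclass
class KFModelParams:
    """Process-noise level and initial conditions of the tracker.

    ``sigma_alpha`` is the random-acceleration std per axis (m/s^2).  The
    initial state defaults to the first observation with zero velocity and
    unit diagonal covariance.
    """

    sigma_alpha: tuple = (0.5, 0.5)
    initial_state: np.ndarray | None = None
    initial_covariance: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        sa = np.broadcast_to(np.asarray(self.sigma_alpha, dtype=float), (2,))
        if np.any(sa < 0):
            raise ValueError("sigma_alpha must be non-negative")
        self.sigma_alpha = tuple(sa)
        self.initial_covariance = np.asarray(self.initial_covariance, dtype=float)
        if not np.allclose(self.initial_covariance, self.initial_covariance.T):
            raise ValueError("initial_covariance must be symmetric")


@dataclass
class KFState:
    state: np.ndarray  # [x, vx, y, vy]
    covariance: np.ndarray  # 4x4
    time: float

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=float).ravel()
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.state.shape != (4,) or self.covariance.shape != (4, 4):
            raise ValueError("state must be a 4-vector with a 4x4 covariance")

    @property
    def position(self) -> np.ndarray:
        return self.state[[0, 2]]

    @property
    def velocity(self) -> np.ndarray:
        return self.state[[1, 3]]


@dataclass
class Observation:
    time: float
    z: np.ndarray
    covariance: np.ndarray
    source: str = "sensor"

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).ravel()
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.z.shape != (2,) or self.covariance.shape != (2, 2):
            raise ValueError("observation must be a 2-vector with a 2x2 covariance")


@dataclass
class KFStepDiagnostics:
    pre_state: np.ndarray
    pre_covariance: np.ndarray
    predicted_observation: np.ndarray
    innovation: np.ndarray
    innovation_covariance: np.ndarray
    gain: np.ndarray
    process_noise: np.ndarray


def transition_matrix(dt: float) -> np.ndarray:
    return np.array(
        [
            [1.0, dt, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, dt],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def process_noise(dt: float, params: KFModelParams) -> np.ndarray:
    """Blockwise white-acceleration process noise: per axis
    sigma^2 * [[dt^4/4, dt^3/2], [dt^3/2, dt^2]]."""
    q = np.zeros((4, 4))
    for axis, sigma in enumerate(params.sigma_alpha):
        block = sigma**2 * np.array(
            [[0.25 * dt**4, 0.5 * dt**3], [0.5 * dt**3, dt**2]]
        )
        i = 2 * axis
        q[i : i + 2, i : i + 2] = block
    return q


def _symmetrise(p: np.ndarray) -> np.ndarray:
    return 0.5 * (p + p.T)


def kf_predict(
    state: KFState, dt: float, params: KFModelParams
) -> tuple[KFState, np.ndarray]:
    """Propagate the state over ``dt`` seconds; returns the pre-estimate and Q."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    f = transition_matrix(dt)
    q = process_noise(dt, params)
    pre = KFState(
        state=f @ state.state,
        covariance=_symmetrise(f @ state.covariance @ f.T + q),
        time=state.time + dt,
    )
    return pre, q


def kf_update(
    pre: KFState, obs: Observation, q: np.ndarray | None = None
) -> tuple[KFState, KFStepDiagnostics]:
    """Fold one observation into the pre-estimate (innovation form)."""
    z_hat = H @ pre.state
    innovation = obs.z - z_hat
    s = H @ pre.covariance @ H.T + obs.covariance
    if abs(np.linalg.det(s)) < 1e-300 or np.linalg.cond(s) > 1e14:
        raise np.linalg.LinAlgError(
            "singular innovation covariance: both the prior and the observation "
            "carry no uncertainty in some direction"
        )
    gain = pre.covariance @ H.T @ np.linalg.inv(s)
    post = KFState(
        state=pre.state + gain @ innovation,
        covariance=_symmetrise((np.eye(4) - gain @ H) @ pre.covariance),
        time=obs.time,
    )
    diag = KFStepDiagnostics(
        pre_state=pre.state.copy(),
        pre_covariance=pre.covariance.copy(),
        predicted_observation=z_hat,
        innovation=innovation,
        innovation_covariance=s,
        gain=gain,
        process_noise=np.zeros((4, 4)) if q is None else q,
    )
    return post, diag


def _merge_observations(radar: SensorTrack, depth: SensorTrack) -> list[Observation]:
    obs = [
        Observation(time=t, z=z, covariance=c, source=track.sensor_id)
        for track in (radar, depth)
        for t, z, c in zip(track.t, track.xy, track.cov)
    ]
    # stable sort on time; radar precedes depth at identical timestamps
    order = {"radar": 0, "depth": 1}
    obs.sort(key=lambda o: (o.time, order.get(o.source, 2)))
    return obs


def kf_fuse_tracks(
    radar: SensorTrack, depth: SensorTrack, params: KFModelParams | None = None
) -> FusedTrack:
    """Run the filter over the merged, time-ordered observation stream.

    Each observation is assimilated with its own noise covariance; the
    posterior position at every observation time is the fused track.  At
    identical timestamps the radar observation is processed first and the
    prediction step is skipped for the second (dt = 0), which is equivalent
    to a single batch update with both observations stacked.
    """
    params = params or KFModelParams()
    stream = _merge_observations(radar, depth)
    if not stream:
        warnings.warn("no observations to fuse: returning an empty track")
        return FusedTrack(t=np.empty(0), xy=np.empty((0, 2)), source="kf")

    first = stream[0]
    if params.initial_state is not None:
        x0 = np.asarray(params.initial_state, dtype=float)
    else:
        x0 = np.array([first.z[0], 0.0, first.z[1], 0.0])
    state = KFState(state=x0, covariance=params.initial_covariance.copy(), time=first.time)
    state, _ = kf_update(state, first)

    times, positions, velocities, covs = [first.time], [state.position], [state.velocity], [
        state.covariance
    ]
    for obs in stream[1:]:
        dt = obs.time - state.time
        pre, q = kf_predict(state, dt, params) if dt > 0 else (state, None)
        state, _ = kf_update(pre, obs, q)
        times.append(obs.time)
        positions.append(state.position)
        velocities.append(state.velocity)
        covs.append(state.covariance)

    t = np.asarray(times)
    # at duplicate timestamps keep the final (fully fused) estimate
    keep = np.concatenate([np.diff(t) > 0, [True]])
    return FusedTrack(
        t=t[keep],
        xy=np.asarray(positions)[keep],
        vel=np.asarray(velocities)[keep],
        cov=np.asarray(covs)[keep],
        source="kf",
    )
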