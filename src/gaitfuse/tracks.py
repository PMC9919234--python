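"""Core containers for timestamped 2-D position data.

Three kinds of tracks circulate in the package:

* :class:`Trajectory` — a ground-truth (reference) path of the walking
  person, typically generated from waypoints at constant speed.
* :class:`SensorTrack` — positions observed by one sensor (impulse radar or
  depth camera), each sample carrying a 2x2 observation-noise covariance.
  Occlusion is represented by samples simply being absent.
* :class:`FusedTrack` — the output of a fusion method; the Kalman fuser
  additionally carries velocities and the 4x4 state covariance.

All positions are in metres, timestamps in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory", "SensorTrack", "FusedTrack"]


def _as_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float).ravel()
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("timestamps must be strictly increasing")
    return t


def _as_xy(xy, n: int) -> np.ndarray:
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("positions must be an (N, 2) array of x-y pairs")
    if xy.shape[0] != n:
        raise ValueError("positions and timestamps must have equal length")
    return xy


@dataclass
class Trajectory:
    """Reference (ground-truth) path of the walking person."""

    t: np.ndarray
    xy: np.ndarray
    walking_speed: float | None = None

    def __post_init__(self) -> None:
        self.t = _as_time(self.t)
        self.xy = _as_xy(self.xy, self.t.size)

    def __len__(self) -> int:
        return self.t.size

    def position_at(self, times) -> np.ndarray:
        """Linearly interpolate the reference position at arbitrary times."""
        times = np.asarray(times, dtype=float)
        x = np.interp(times, self.t, self.xy[:, 0])
        y = np.interp(times, self.t, self.xy[:, 1])
        return np.column_stack([x, y])


@dataclass
class SensorTrack:
    """Observed positions from one sensor with per-sample noise covariance.

    ``cov`` has shape (N, 2, 2); each matrix must be symmetric positive
    semi-definite.  Gaps (occlusion) are encoded by absent samples, so the
    timestamps of a fragmented track are still strictly increasing but no
    longer equispaced.
    """

    sensor_id: str
    t: np.ndarray
    xy: np.ndarray
    cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = _as_time(self.t)
        self.xy = _as_xy(self.xy, self.t.size)
        if self.cov is None:
            self.cov = np.zeros((self.t.size, 2, 2))
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (self.t.size, 2, 2):
            raise ValueError("cov must have shape (N, 2, 2)")
        if self.t.size:
            if not np.allclose(self.cov, np.swapaxes(self.cov, 1, 2), atol=1e-12):
                raise ValueError("noise covariances must be symmetric")
            if np.any(np.linalg.eigvalsh(self.cov) < -1e-9):
                raise ValueError("noise covariances must be positive semi-definite")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class FusedTrack:
    """Fused position estimates; velocity/covariance present for the KF."""

    t: np.ndarray
    xy: np.ndarray
    vel: np.ndarray | None = None
    cov: np.ndarray | None = None  # (N, 4, 4) state covariance, KF only
    source: str = "fused"

    def __post_init__(self) -> None:
        self.t = _as_time(self.t)
        self.xy = _as_xy(self.xy, self.t.size)
        if self.vel is not None:
            self.vel = _as_xy(self.vel, self.t.size)
        if self.cov is not None:
            self.cov = np.asarray(self.cov, dtype=float)
            if self.cov.shape != (self.t.size, 4, 4):
                raise ValueError("cov must have shape (N, 4, 4)")

    def __len__(self) -> int:
        return self.t.size
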