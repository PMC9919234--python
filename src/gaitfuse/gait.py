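"""Extraction of healthcare-related gait parameters from a position track.

From a timestamped 2-D position sequence (raw sensor data or fused
estimates) the module extracts:

* a binary **motion indicator** — motion is declared at sample n when the
  distance travelled over the trailing window T_m exceeds the threshold D,
  prorated by the actual window span: d_n > ((t_n - t_{n0}) / T_m) * D,
  where n0 is the earliest sample with t >= t_n - T_m;
* a binary **turn indicator** — a turn is declared when the absolute
  windowed sum of successive heading changes over T_t lies strictly
  between the angle threshold Phi and pi.  Headings are four-quadrant
  arctangents of consecutive displacements; heading differences are
  wrapped into (-pi, pi] per step, and zero-displacement steps carry the
  previous heading (contributing nothing to the sum);
* the **travelled distance** (sum of consecutive segment lengths), the
  **time in motion**, and the **mean walking speed** (distance divided by
  time in motion).

Both binary indicators are post-processed by 1-D morphological closing with
a flat structuring element spanning the detection window, which fills short
drop-outs caused by the dispersion of the position estimates.  Turns are
counted as rising edges of the closed turn indicator.

Defaults T_m = 0.45 s, D = 0.1 m, T_t = 1 s, Phi = 60 deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "MotionDetectionConfig",
    "TurnDetectionConfig",
    "BinaryIndicator",
    "GaitSummary",
    "detect_motion",
    "morphological_close",
    "detect_turns",
    "travelled_distance",
    "time_in_motion",
    "mean_walking_speed",
    "smooth_track",
    "summarize_gait",
]


@dataclass
class MotionDetectionConfig:
    T_m: float = 0.45  # trailing window, seconds
    D: float = 0.1  # displacement threshold, metres

    def __post_init__(self) -> None:
        if self.T_m <= 0 or self.D <= 0:
            raise ValueError("T_m and D must be positive")


@dataclass
class TurnDetectionConfig:
    T_t: float = 1.0  # trailing window, seconds
    Phi: float = math.radians(60.0)  # heading-change threshold, radians

    def __post_init__(self) -> None:
        if self.T_t <= 0:
            raise ValueError("T_t must be positive")
        if not 0 < self.Phi < math.pi:
            raise ValueError("Phi must lie in (0, pi)")


@dataclass
class BinaryIndicator:
    t: np.ndarray
    values: np.ndarray
    kind: str  # "motion" or "turn"
    closed: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values).astype(np.uint8)
        if self.t.shape != self.values.shape:
            raise ValueError("timestamps and values must have equal length")
        if np.any(self.values > 1):
            raise ValueError("indicator values must be 0 or 1")

    def intervals(self) -> list[tuple[float, float]]:
        """(start, stop) times of contiguous 1-runs."""
        v = self.values
        edges = np.flatnonzero(np.diff(np.concatenate([[0], v, [0]])))
        return [(self.t[a], self.t[b - 1]) for a, b in zip(edges[::2], edges[1::2])]


@dataclass
class GaitSummary:
    n_turns: int
    distance: float
    time_in_motion: float
    mean_speed: float  # NaN when no motion was detected
    motion_intervals: list = field(default_factory=list)
    turn_intervals: list = field(default_factory=list)


def _check_track(t, xy, min_samples=1):
    t = np.asarray(t, dtype=float).ravel()
    xy = np.asarray(xy, dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("timestamps must be strictly increasing")
    if xy.shape != (t.size, 2):
        raise ValueError("track must be (N, 2) positions with N timestamps")
    if t.size < min_samples:
        raise ValueError(f"at least {min_samples} samples are required")
    return t, xy


def _window_start(t: np.ndarray, horizon: float) -> np.ndarray:
    """Earliest index n0 with t[n0] >= t[n] - horizon, clipped to n-1."""
    n0 = np.searchsorted(t, t - horizon, side="left")
    return np.minimum(n0, np.maximum(np.arange(t.size) - 1, 0))


def detect_motion(t, xy, cfg: MotionDetectionConfig | None = None) -> BinaryIndicator:
    """Binary motion indicator from windowed displacement."""
    cfg = cfg or MotionDetectionConfig()
    t, xy = _check_track(t, xy, min_samples=2)
    n0 = _window_start(t, cfg.T_m)
    disp = np.hypot(xy[:, 0] - xy[n0, 0], xy[:, 1] - xy[n0, 1])
    b = disp > ((t - t[n0]) / cfg.T_m) * cfg.D
    b[0] = False
    return BinaryIndicator(t=t, values=b, kind="motion")


def _structuring_length(t: np.ndarray, window: float) -> int:
    """Number of data points within the time window at the track's rate."""
    dt = np.median(np.diff(t)) if t.size > 1 else 1.0
    return max(1, int(math.floor(window / dt + 1e-9)) + 1)


def morphological_close(indicator: BinaryIndicator, window: float) -> BinaryIndicator:
    """1-D binary closing (dilation then erosion) with a flat element.

    The element length equals the number of samples spanning ``window``
    seconds at the track's sampling rate.  The sequence is treated as
    embedded in an infinite all-zero background, so closing is extensive
    (never removes ones) and idempotent.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    length = _structuring_length(indicator.t, window)
    v = indicator.values.astype(bool)
    pad = length
    padded = np.pad(v, pad)
    closed = ndimage.binary_closing(padded, structure=np.ones(length, dtype=bool))
    return BinaryIndicator(
        t=indicator.t, values=closed[pad:-pad], kind=indicator.kind, closed=True
    )


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    return math.pi - np.mod(math.pi - np.asarray(a), 2.0 * math.pi)


def detect_turns(
    t, xy, cfg: TurnDetectionConfig | None = None
) -> tuple[BinaryIndicator, int]:
    """Turn indicator and turn count.

    Returns the *closed* indicator (closing window T_t) and the number of
    rising edges, i.e. the number of distinct turn events.
    """
    cfg = cfg or TurnDetectionConfig()
    t, xy = _check_track(t, xy, min_samples=3)
    d = np.diff(xy, axis=0)
    moving = (d[:, 0] != 0) | (d[:, 1] != 0)
    heading = np.arctan2(d[:, 1], d[:, 0])
    if not moving.all():
        # zero-displacement steps carry the previous (or first defined) heading
        if moving.any():
            idx = np.where(moving, np.arange(d.shape[0]), -1)
            idx = np.maximum.accumulate(idx)
            idx[idx < 0] = np.argmax(moving)
            heading = heading[idx]
        else:
            heading = np.zeros(d.shape[0])
    dh = _wrap_angle(np.diff(heading))  # dh[j] is the change at step j+2
    dh = np.where(np.abs(np.diff(heading)) == 0, 0.0, dh)
    csum = np.concatenate([[0.0], np.cumsum(dh)])  # csum[k] = sum(dh[:k])

    n = t.size
    n0 = _window_start(t, cfg.T_t)
    b = np.zeros(n, dtype=bool)
    for i in range(2, n):
        start = n0[i] + 2  # first step index contributing: nu = n0 + 2
        if start > i:
            continue
        total = abs(csum[i - 1] - csum[start - 2])
        b[i] = cfg.Phi < total < math.pi
    raw = BinaryIndicator(t=t, values=b, kind="turn")
    closed = morphological_close(raw, cfg.T_t)
    v = closed.values
    n_turns = int(v[0]) + int(np.sum((v[1:] == 1) & (v[:-1] == 0)))
    return closed, n_turns


def travelled_distance(xy) -> float:
    """Sum of Euclidean distances between consecutive positions."""
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 1:
        raise ValueError("positions must be a non-empty (N, 2) array")
    d = np.diff(xy, axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def time_in_motion(indicator: BinaryIndicator) -> float:
    """Total duration where the (closed) motion indicator is 1.

    Each sample owns the span between the midpoints to its neighbours; the
    first and last samples own half of their single adjacent interval.
    """
    t, v = indicator.t, indicator.values.astype(bool)
    if t.size < 2:
        return 0.0
    mid = (t[:-1] + t[1:]) / 2.0
    left = np.concatenate([[t[0]], mid])
    right = np.concatenate([mid, [t[-1]]])
    return float(np.sum((right - left)[v]))


def mean_walking_speed(t, xy, motion: BinaryIndicator, restrict_to_motion=False) -> float:
    """Travelled distance divided by time in motion; NaN if never moving.

    With ``restrict_to_motion`` the distance sum only includes segments whose
    endpoints both lie in motion intervals.
    """
    t, xy = _check_track(t, xy)
    if motion.t.shape != t.shape:
        raise ValueError("motion indicator is not aligned with the track")
    tim = time_in_motion(motion)
    if tim <= 0:
        return float("nan")
    if restrict_to_motion:
        v = motion.values.astype(bool)
        seg = v[:-1] & v[1:]
        d = np.diff(xy, axis=0)
        dist = float(np.sum(np.hypot(d[:, 0], d[:, 1])[seg]))
    else:
        dist = travelled_distance(xy)
    return dist / tim


def smooth_track(t, xy, window: float):
    """Centred moving-average smoothing of the coordinates.

    The window is given in seconds and converted to an odd sample count at
    the track's rate; edge windows shrink.  Timestamps are unchanged.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    t, xy = _check_track(t, xy)
    length = _structuring_length(t, window)
    if length % 2 == 0:
        length += 1
    if length <= 1 or t.size < 2:
        return t.copy(), xy.copy()
    sm = (
        pd.DataFrame(xy)
        .rolling(window=length, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return t.copy(), sm


def summarize_gait(
    t,
    xy,
    motion_cfg: MotionDetectionConfig | None = None,
    turn_cfg: TurnDetectionConfig | None = None,
    restrict_speed_to_motion: bool = False,
) -> GaitSummary:
    """Full gait-parameter extraction for one track."""
    motion_cfg = motion_cfg or MotionDetectionConfig()
    turn_cfg = turn_cfg or TurnDetectionConfig()
    t = np.asarray(t, dtype=float)
    motion = morphological_close(detect_motion(t, xy, motion_cfg), motion_cfg.T_m)
    turns, n_turns = detect_turns(t, xy, turn_cfg)
    return GaitSummary(
        n_turns=n_turns,
        distance=travelled_distance(xy),
        time_in_motion=time_in_motion(motion),
        mean_speed=mean_walking_speed(
            t, xy, motion, restrict_to_motion=restrict_speed_to_motion
        ),
        motion_intervals=motion.intervals(),
        turn_intervals=turns.intervals(),
    )
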