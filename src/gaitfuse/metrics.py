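"""Uncertainty indicators for position estimates and gait parameters.

Position errors are computed per realisation against the reference path
(linearly interpolated at the estimate timestamps): coordinate errors
dx, dy and the position error dd = sqrt(dx^2 + dy^2).  Pooled over all
realisations, the errors are summarised by their empirical cumulative
distribution function F(xi) and by:

* AECDF — the area under F over xi in [0, 1] m (1 is perfect),
* MEAE / MEDE / MAXE / STDE — mean, median, maximum and standard
  deviation of the pooled position errors.

Gait-parameter estimates (number of turns, travelled distance, mean
walking speed) are summarised across realisations by the mean error (ME)
against the reference value and the standard deviation of that error (SE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.distributions.empirical_distribution import ECDF

from .gait import GaitSummary
from .tracks import Trajectory

__all__ = [
    "ErrorSequence",
    "ECDFSummary",
    "ParamErrorSummary",
    "position_errors",
    "pool_errors",
    "ecdf_and_indicators",
    "parameter_errors",
]

GAIT_PARAMETERS = ("n_turns", "distance", "mean_speed")


@dataclass
class ErrorSequence:
    """Absolute position-estimation errors of one realisation."""

    dx: np.ndarray
    dy: np.ndarray
    dd: np.ndarray
    realisation: int = 0

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        self.dd = np.asarray(self.dd, dtype=float)

    def __len__(self) -> int:
        return self.dd.size


@dataclass
class ECDFSummary:
    xi: np.ndarray  # breakpoints of the step ECDF
    F: np.ndarray  # F evaluated at the breakpoints (right-continuous)
    aecdf: float
    meae: float
    mede: float
    maxe: float
    stde: float


@dataclass
class ParamErrorSummary:
    parameter: str
    me: float
    se: float
    n: int


def position_errors(estimate, reference: Trajectory, realisation: int = 0) -> ErrorSequence:
    """Errors of a track against the reference, per sample.

    Estimate samples outside the reference time span are dropped with a
    warning; the reference is interpolated linearly at the remaining
    timestamps.
    """
    t = np.asarray(estimate.t, dtype=float)
    xy = np.asarray(estimate.xy, dtype=float)
    inside = (t >= reference.t[0]) & (t <= reference.t[-1])
    if not inside.all():
        warnings.warn(
            f"dropping {int((~inside).sum())} samples outside the reference time span"
        )
    t, xy = t[inside], xy[inside]
    ref = reference.position_at(t)
    dx = xy[:, 0] - ref[:, 0]
    dy = xy[:, 1] - ref[:, 1]
    return ErrorSequence(dx=dx, dy=dy, dd=np.hypot(dx, dy), realisation=realisation)


def pool_errors(sequences) -> np.ndarray:
    """Concatenate per-realisation position errors into one pooled sample."""
    seqs = [s.dd if isinstance(s, ErrorSequence) else np.asarray(s) for s in sequences]
    return np.concatenate(seqs) if seqs else np.empty(0)


def ecdf_and_indicators(errors) -> ECDFSummary:
    """Step ECDF of pooled position errors plus the scalar indicators.

    The AECDF is the exact integral of the step function over [0, 1] m (no
    grid discretisation).  STDE uses the n-1 denominator (0 for a single
    error value).
    """
    dd = errors.dd if isinstance(errors, ErrorSequence) else np.asarray(errors, float)
    dd = dd.ravel()
    if dd.size == 0:
        raise ValueError("at least one error value is required")
    if np.any(dd < 0):
        raise ValueError("position errors must be non-negative")

    ecdf = ECDF(dd)
    xi = np.unique(dd)
    f_at = ecdf(xi)

    # exact integral of the right-continuous step function over [0, 1]
    edges = np.unique(np.concatenate([[0.0], xi[(xi > 0) & (xi < 1)], [1.0]]))
    widths = np.diff(edges)
    f_left = ecdf(edges[:-1])  # constant on [edge_i, edge_{i+1})
    aecdf = float(np.sum(f_left * widths))

    stde = float(np.std(dd, ddof=1)) if dd.size > 1 else 0.0
    return ECDFSummary(
        xi=xi,
        F=f_at,
        aecdf=aecdf,
        meae=float(np.mean(dd)),
        mede=float(np.median(dd)),
        maxe=float(np.max(dd)),
        stde=stde,
    )


def parameter_errors(
    estimates: list[GaitSummary], references: list[GaitSummary]
) -> dict[str, ParamErrorSummary]:
    """ME and SE of each gait parameter over paired realisations."""
    if len(estimates) != len(references):
        raise ValueError("estimates and references must be paired lists of equal length")
    if not estimates:
        raise ValueError("at least one realisation is required")
    out = {}
    for name in GAIT_PARAMETERS:
        err = np.array(
            [getattr(e, name) - getattr(r, name) for e, r in zip(estimates, references)],
            dtype=float,
        )
        se = float(np.std(err, ddof=1)) if err.size > 1 else 0.0
        out[name] = ParamErrorSummary(parameter=name, me=float(np.mean(err)), se=se, n=err.size)
    return out
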