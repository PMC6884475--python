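"""Driving-performance metrics computed from a trial log.

Two scalar metrics summarise each one-minute trial; for both, lower is
better:

* **SDLP** — the standard deviation of lateral position over the whole
  trial (m).  It indexes lane-keeping *accuracy*, which is dominated by
  compensatory (feedback) steering from near-road position information.
* **SWV** — the mean, over bends, of the per-bend maximum absolute
  steering-wheel velocity (deg/s).  It indexes steering *stability*, which
  is dominated by anticipatory (feedforward) steering from previewed road
  curvature.

SDLP uses the sample (N-1) standard deviation; at 3600 samples per trial
the distinction from the population form is negligible.  Steering-wheel
velocity is the central finite difference of the logged wheel angle at the
simulation rate, without smoothing.  A "curve negotiation" window is a
maximal run of records whose centreline projection lies in an arc segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .course import RoadCourse
from .vehicle import TrialLog

__all__ = ["TrialMetrics", "sdlp", "curve_windows", "swv", "trial_metrics"]


@dataclass(frozen=True)
class TrialMetrics:
    """Per-trial performance summary.

    ``swv`` is NaN when the trial contains no curve window.
    """

    sdlp: float
    swv: float
    n_curves: int
    off_road: bool


def sdlp(log: TrialLog) -> float:
    """Standard deviation of lateral position over the trial, m."""
    if len(log) == 0:
        raise ValueError("empty trial log")
    return float(np.std(log.deviation, ddof=1)) if len(log) > 1 else 0.0


def _arc_mask(log: TrialLog, course: RoadCourse) -> np.ndarray:
    starts = course._start_s
    idx = np.clip(
        np.searchsorted(starts, log.s_proj, side="right") - 1,
        0,
        len(course.segments) - 1,
    )
    return course._is_arc[idx]


def curve_windows(log: TrialLog, course: RoadCourse) -> list[tuple[float, float]]:
    """Maximal time intervals the vehicle's projection spends in bends.

    Returns ordered, non-overlapping ``(t_start, t_end)`` pairs; a window
    that is still open when the trial ends is truncated at the last record.
    """
    spans = _curve_spans(log, course)
    t = log.t
    return [(float(t[a]), float(t[b - 1])) for a, b in spans]


def _curve_spans(log: TrialLog, course: RoadCourse) -> list[tuple[int, int]]:
    """Half-open index ranges ``[a, b)`` of the curve windows."""
    mask = _arc_mask(log, course)
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def sw_velocity(log: TrialLog) -> np.ndarray:
    """Central-difference steering-wheel velocity, rad/s (one-sided at the ends)."""
    return np.gradient(log.sw_angle, log.dt)


def swv(log: TrialLog, course: RoadCourse) -> float:
    """Mean per-curve maximum absolute steering-wheel velocity, deg/s.

    NaN when the trial contains no curve window (a missing value, not a
    zero: with no bends there is nothing to negotiate).
    """
    spans = _curve_spans(log, course)
    if not spans:
        return math.nan
    vel = np.degrees(np.abs(sw_velocity(log)))
    return float(np.mean([vel[a:b].max() for a, b in spans]))


def trial_metrics(log: TrialLog, course: RoadCourse) -> TrialMetrics:
    """Compute both performance metrics for one trial."""
    spans = _curve_spans(log, course)
    return TrialMetrics(
        sdlp=sdlp(log),
        swv=swv(log, course),
        n_curves=len(spans),
        off_road=log.off_road,
    )
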