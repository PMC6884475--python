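"""Procedural winding road courses.

A course is an ordered sequence of straight and circular-arc segments with
piecewise-constant curvature, parameterised by arc length ``s``.  Straights
alternate with bends, and successive bends alternate turning direction, so a
course reads straight, left bend, straight, right bend, ... (or starting with
a right bend).  Geometry is planar.

Sign conventions, used throughout the package:

* positive curvature = left-hand bend (counter-clockwise);
* positive lateral deviation = vehicle left of the lane centre, measured
  along the local left normal of the centreline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Segment",
    "RoadCourse",
    "OffRoadError",
    "generate_course",
    "centerline_pose",
    "lateral_deviation",
    "DEFAULT_CURV_RANGE",
    "DEFAULT_STRAIGHT_RANGE",
    "DEFAULT_BEND_LENGTH_RANGE",
    "DEFAULT_LANE_WIDTH",
]

#: Bend curvature magnitudes are drawn uniformly from this range (1/m).
DEFAULT_CURV_RANGE = (1.0 / 180.0, 1.0 / 80.0)
#: Straight-section lengths are drawn uniformly from this range (m).
DEFAULT_STRAIGHT_RANGE = (50.0, 150.0)
#: Bend arc lengths are drawn uniformly from this range (m).
DEFAULT_BEND_LENGTH_RANGE = (50.0, 150.0)
#: Lane width (m); the distance between the left and right lane marks.
DEFAULT_LANE_WIDTH = 3.5


class OffRoadError(ValueError):
    """Raised when a query point lies implausibly far from the centreline."""

    def __init__(self, deviation: float, s_proj: float, bound: float):
        self.deviation = deviation
        self.s_proj = s_proj
        self.bound = bound
        super().__init__(
            f"point is {abs(deviation):.2f} m from the lane centre "
            f"(sanity bound {bound:.2f} m)"
        )


@dataclass(frozen=True)
class Segment:
    """One piecewise-constant-curvature piece of the centreline.

    Parameters
    ----------
    kind
        ``"straight"`` or ``"arc"``.
    length
        Arc length of the segment, m (> 0).
    curvature
        Signed curvature, 1/m.  Zero for straights; positive = left bend.
    start_s
        Arc-length position of the segment start along the course, m.
    """

    kind: str
    length: float
    curvature: float
    start_s: float

    def __post_init__(self):
        if self.kind not in ("straight", "arc"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.length > 0:
            raise ValueError("segment length must be positive")
        if self.kind == "straight" and self.curvature != 0.0:
            raise ValueError("straight segments must have zero curvature")
        if self.kind == "arc" and self.curvature == 0.0:
            raise ValueError("arc segments must have nonzero curvature")

    @property
    def end_s(self) -> float:
        return self.start_s + self.length


class RoadCourse:
    """A road course: contiguous segments plus a lane width.

    The constructor precomputes, for every segment, the pose of its start
    point (closed-form integration of the piecewise-clothoid-free path), so
    that pose and projection queries are O(log n) / O(1).
    """

    def __init__(self, segments: Sequence[Segment], lane_width: float = DEFAULT_LANE_WIDTH):
        if not segments:
            raise ValueError("a course needs at least one segment")
        if lane_width <= 0:
            raise ValueError("lane_width must be positive")
        s = 0.0
        for seg in segments:
            if not math.isclose(seg.start_s, s, rel_tol=0.0, abs_tol=1e-9):
                raise ValueError("segments must be contiguous and start at s=0")
            s += seg.length
        self.segments = tuple(segments)
        self.lane_width = float(lane_width)
        self.total_length = s
        self._build_tables()

    def _build_tables(self) -> None:
        n = len(self.segments)
        self._start_s = np.empty(n + 1)
        self._kappa = np.empty(n)
        self._is_arc = np.empty(n, dtype=bool)
        self._x0 = np.empty(n)
        self._y0 = np.empty(n)
        self._h0 = np.empty(n)
        x, y, h = 0.0, 0.0, 0.0
        for i, seg in enumerate(self.segments):
            self._start_s[i] = seg.start_s
            self._kappa[i] = seg.curvature
            self._is_arc[i] = seg.kind == "arc"
            self._x0[i], self._y0[i], self._h0[i] = x, y, h
            x, y, h = _advance(x, y, h, seg.curvature, seg.length)
        self._start_s[n] = self.total_length
        self._end_pose = (x, y, h)

    # -- queries ---------------------------------------------------------

    def segment_index(self, s: float) -> int:
        """Index of the segment containing arc position ``s``.

        At interior joints the later segment wins; ``s == total_length``
        maps to the last segment.
        """
        if not (0.0 <= s <= self.total_length):
            raise ValueError(f"s={s} outside course [0, {self.total_length}]")
        i = int(np.searchsorted(self._start_s, s, side="right")) - 1
        return min(i, len(self.segments) - 1)

    def pose(self, s: float) -> tuple[float, float, float, float]:
        """Centreline pose ``(x, y, heading, curvature)`` at arc position ``s``."""
        i = self.segment_index(s)
        ds = s - self._start_s[i]
        x, y, h = _advance(self._x0[i], self._y0[i], self._h0[i], self._kappa[i], ds)
        return x, y, h, self._kappa[i]

    def curvature_at(self, s: float) -> float:
        return self._kappa[self.segment_index(s)]

    def kind_at(self, s: float) -> str:
        return "arc" if self._is_arc[self.segment_index(s)] else "straight"

    def project(self, x: float, y: float, s_hint: float) -> tuple[float, float]:
        """Signed lateral offset and foot-point arc position of ``(x, y)``.

        A local search walks segment-to-segment from the segment containing
        ``s_hint``; it is exact for points whose perpendicular foot lies
        within a few segments of the hint (the closed-loop simulation moves
        the hint forward every step, so one or two hops suffice).  Ties at
        joints resolve to the smaller ``s``.
        """
        d, s, _, _ = self._project_full(x, y, s_hint)
        return d, s

    def _project_full(self, x: float, y: float, s_hint: float) -> tuple[float, float, float, bool]:
        """Like :meth:`project` but also returns tangent heading and arc flag."""
        start_s = self._start_s
        i = self.segment_index(s_hint)
        n = len(self.segments)
        for _ in range(32):
            x0, y0, h0, kap = self._x0[i], self._y0[i], self._h0[i], self._kappa[i]
            seg_len = start_s[i + 1] - start_s[i]
            if kap == 0.0:
                ch, sh = math.cos(h0), math.sin(h0)
                dx, dy = x - x0, y - y0
                s_loc = dx * ch + dy * sh
                dev = -dx * sh + dy * ch
                h_foot = h0
            else:
                # circle centre lies at 1/kappa along the left normal
                cx = x0 - math.sin(h0) / kap
                cy = y0 + math.cos(h0) / kap
                wx, wy = x - cx, y - cy
                psi = math.atan2(wy, wx)
                h_foot = psi + math.copysign(math.pi / 2.0, kap)
                dh = _wrap_pi(h_foot - h0)
                s_loc = dh / kap
                dev = 1.0 / kap - math.copysign(math.hypot(wx, wy), kap)
                h_foot = h0 + kap * max(0.0, min(s_loc, seg_len))
            if s_loc < 0.0 and i > 0:
                i -= 1
                continue
            if s_loc > seg_len and i < n - 1:
                i += 1
                continue
            s_loc = max(0.0, min(s_loc, seg_len))
            return dev, start_s[i] + s_loc, h_foot, bool(self._is_arc[i])
        # pathological ping-pong cannot happen on a C1 path; clamp and return
        s_loc = max(0.0, min(s_loc, seg_len))
        return dev, start_s[i] + s_loc, h_foot, bool(self._is_arc[i])

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "lane_width": self.lane_width,
            "segments": [
                {
                    "kind": seg.kind,
                    "length": seg.length,
                    "curvature": seg.curvature,
                    "start_s": seg.start_s,
                }
                for seg in self.segments
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "RoadCourse":
        segs = [
            Segment(e["kind"], e["length"], e["curvature"], e["start_s"])
            for e in d["segments"]
        ]
        return cls(segs, lane_width=d["lane_width"])

    @classmethod
    def from_json(cls, text: str) -> "RoadCourse":
        return cls.from_dict(json.loads(text))

    def __repr__(self) -> str:
        n_arc = int(self._is_arc.sum())
        return (
            f"RoadCourse({len(self.segments)} segments, {n_arc} bends, "
            f"{self.total_length:.1f} m, lane {self.lane_width} m)"
        )


def _advance(x: float, y: float, h: float, kappa: float, ds: float) -> tuple[float, float, float]:
    """Closed-form pose advance along a constant-curvature piece."""
    if kappa == 0.0:
        return x + ds * math.cos(h), y + ds * math.sin(h), h
    h2 = h + kappa * ds
    return (
        x + (math.sin(h2) - math.sin(h)) / kappa,
        y - (math.cos(h2) - math.cos(h)) / kappa,
        h2,
    )


def _wrap_pi(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def generate_course(
    seed: int,
    total_length: float = 1500.0,
    curv_range: tuple[float, float] = DEFAULT_CURV_RANGE,
    straight_range: tuple[float, float] = DEFAULT_STRAIGHT_RANGE,
    bend_length_range: tuple[float, float] = DEFAULT_BEND_LENGTH_RANGE,
    lane_width: float = DEFAULT_LANE_WIDTH,
) -> RoadCourse:
    """Generate a seeded random course of alternating straights and bends.

    Bend curvature magnitudes are uniform on ``curv_range``; straight and
    bend lengths are uniform on their ranges.  Successive bends strictly
    alternate turning direction; the first bend's direction is random.
    Segments are appended until the accumulated length reaches
    ``total_length`` (the last segment may overshoot), so
    ``course.total_length >= total_length``.

    The same seed always yields the same course.
    """
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    for name, (lo, hi) in (
        ("curv_range", curv_range),
        ("straight_range", straight_range),
        ("bend_length_range", bend_length_range),
    ):
        if not (0 < lo <= hi):
            raise ValueError(f"{name} must satisfy 0 < lo <= hi, got {(lo, hi)}")
    rng = np.random.default_rng(seed)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    segments: list[Segment] = []
    s = 0.0
    make_straight = True
    while s < total_length:
        if make_straight:
            length = float(rng.uniform(*straight_range))
            segments.append(Segment("straight", length, 0.0, s))
        else:
            length = float(rng.uniform(*bend_length_range))
            kappa = sign * float(rng.uniform(*curv_range))
            segments.append(Segment("arc", length, kappa, s))
            sign = -sign
        s += length
        make_straight = not make_straight
    return RoadCourse(segments, lane_width=lane_width)


def centerline_pose(course: RoadCourse, s: float) -> tuple[float, float, float, float]:
    """Pose ``(x, y, heading, curvature)`` of the lane centre at arc position ``s``."""
    return course.pose(s)


def lateral_deviation(
    course: RoadCourse,
    x: float,
    y: float,
    s_hint: float,
    sanity_factor: float = 3.0,
) -> tuple[float, float]:
    """Signed perpendicular distance from the lane centre, and the foot point.

    Positive deviation means the point lies to the left of the centreline in
    the direction of travel.  Raises :class:`OffRoadError` if the point is
    farther than ``sanity_factor * lane_width`` from the centre; callers that
    tolerate excursions (the trial runner does) should use
    :meth:`RoadCourse.project` directly and flag the trial instead.
    """
    d, s_proj = course.project(x, y, s_hint)
    bound = sanity_factor * course.lane_width
    if abs(d) > bound:
        raise OffRoadError(d, s_proj, bound)
    return d, s_proj
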