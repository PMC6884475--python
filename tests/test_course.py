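"""Road-course generation and geometry queries."""

import json
import math

import numpy as np
import pytest

from lanecue.course import (
    DEFAULT_CURV_RANGE,
    DEFAULT_STRAIGHT_RANGE,
    OffRoadError,
    RoadCourse,
    Segment,
    centerline_pose,
    generate_course,
    lateral_deviation,
)


def _collect_segments(n_min=1000, seed0=0):
    """Segments from as many default courses as needed to reach n_min."""
    segs = []
    seed = seed0
    while len(segs) < n_min:
        segs.extend(generate_course(seed).segments)
        seed += 1
    return segs


class TestGeneration:
    def test_parameter_ranges_and_alternation_over_1000_segments(self):
        segs = _collect_segments(1000)
        assert len(segs) >= 1000
        for s in segs:
            if s.kind == "straight":
                assert s.curvature == 0.0
                assert DEFAULT_STRAIGHT_RANGE[0] <= s.length <= DEFAULT_STRAIGHT_RANGE[1]
            else:
                assert DEFAULT_CURV_RANGE[0] <= abs(s.curvature) <= DEFAULT_CURV_RANGE[1]

    def test_arc_signs_strictly_alternate(self):
        for seed in range(30):
            arcs = [s for s in generate_course(seed).segments if s.kind == "arc"]
            signs = [math.copysign(1, a.curvature) for a in arcs]
            assert all(a == -b for a, b in zip(signs, signs[1:]))

    def test_straights_and_arcs_interleave(self):
        for seed in range(10):
            kinds = [s.kind for s in generate_course(seed).segments]
            assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_contiguity_and_total_length(self):
        c = generate_course(3, total_length=2000.0)
        assert c.total_length >= 2000.0
        s = 0.0
        for seg in c.segments:
            assert seg.start_s == pytest.approx(s, abs=1e-9)
            s += seg.length
        assert c.total_length == pytest.approx(s)

    def test_same_seed_byte_identical_serialization(self):
        a = generate_course(77).to_json()
        b = generate_course(77).to_json()
        assert a == b
        assert generate_course(78).to_json() != a

    def test_round_trip_serialization(self):
        c = generate_course(5)
        c2 = RoadCourse.from_json(c.to_json())
        assert c2.to_dict() == c.to_dict()
        assert json.loads(c.to_json())["lane_width"] == 3.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"total_length": -1.0},
            {"curv_range": (0.0, 0.01)},
            {"straight_range": (150.0, 50.0)},
            {"bend_length_range": (-5.0, 10.0)},
        ],
    )
    def test_bad_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            generate_course(0, **kwargs)


class TestCenterlinePose:
    def test_origin_pose(self, course):
        x, y, h, k = centerline_pose(course, 0.0)
        assert (x, y, h) == (0.0, 0.0, 0.0)

    def test_straight_advance(self, toy_course):
        x1, y1, h1, k1 = centerline_pose(toy_course, 10.0)
        x2, y2, h2, k2 = centerline_pose(toy_course, 60.0)
        assert k1 == k2 == 0.0
        assert h1 == h2
        assert math.hypot(x2 - x1, y2 - y1) == pytest.approx(50.0)

    def test_arc_heading_change(self):
        # quarter circle of radius 100: advancing 157.08 m turns 1.5708 rad
        segs = [Segment("arc", 200.0, 1 / 100.0, 0.0)]
        c = RoadCourse(segs)
        _, _, h0, _ = c.pose(0.0)
        _, _, h1, _ = c.pose(157.08)
        assert h1 - h0 == pytest.approx(1.5708, abs=1e-6)

    def test_out_of_range_raises(self, course):
        with pytest.raises(ValueError):
            course.pose(-0.1)
        with pytest.raises(ValueError):
            course.pose(course.total_length + 0.1)

    def test_agrees_with_frenet_integration(self, course):
        """Closed-form poses match trapezoid integration of x'=cos h, y'=sin h."""
        ds = 0.005
        for seg in course.segments:
            n = int(seg.length / ds) + 1
            s = np.linspace(0.0, seg.length, n)
            x0, y0, h0, k = course.pose(seg.start_s)
            h = h0 + k * s
            x = x0 + np.concatenate([[0.0], np.cumsum((np.cos(h[1:]) + np.cos(h[:-1])) / 2) * np.diff(s)])
            y = y0 + np.concatenate([[0.0], np.cumsum((np.sin(h[1:]) + np.sin(h[:-1])) / 2) * np.diff(s)])
            for frac in (0.25, 0.5, 1.0):
                idx = int((n - 1) * frac)
                s_query = min(seg.start_s + s[idx], course.total_length)
                xq, yq, hq, _ = course.pose(s_query)
                assert xq == pytest.approx(x[idx], abs=1e-6)
                assert yq == pytest.approx(y[idx], abs=1e-6)
                assert hq == pytest.approx(h[idx], abs=1e-9)


class TestLateralDeviation:
    def test_on_centerline_is_zero(self, course):
        for s in np.linspace(0.0, course.total_length, 200):
            x, y, _, _ = course.pose(s)
            d, s_proj = course.project(x, y, s)
            assert abs(d) < 1e-9
            assert s_proj == pytest.approx(s, abs=1e-6)

    def test_normal_offset_round_trip(self, course):
        """Displacing by d along the left normal recovers deviation d."""
        for s in np.linspace(1.0, course.total_length - 1.0, 100):
            for d in (-1.5, -0.3, 0.4, 1.2):
                x, y, h, _ = course.pose(s)
                px, py = x - d * math.sin(h), y + d * math.cos(h)
                dev, s_proj = course.project(px, py, s)
                assert dev == pytest.approx(d, abs=1e-6)
                assert s_proj == pytest.approx(s, abs=1e-6)

    def test_straight_left_offset_positive(self, toy_course):
        x, y, h, _ = toy_course.pose(50.0)
        dev, _ = toy_course.project(x - math.sin(h), y + math.cos(h), 50.0)
        assert dev == pytest.approx(1.0, abs=1e-9)

    def test_arc_offset_against_brute_force(self, toy_course):
        """Projection matches dense nearest-point search on an arc."""
        s0 = 150.0  # mid first arc
        x, y, h, _ = toy_course.pose(s0)
        for d in (0.5, -0.5):
            px, py = x - d * math.sin(h), y + d * math.cos(h)
            dev, s_proj = toy_course.project(px, py, s0)
            # brute force over a densely sampled centreline
            grid = np.arange(0.0, toy_course.total_length, 0.001)
            pts = np.array([toy_course.pose(s)[:2] for s in grid])
            dists = np.hypot(pts[:, 0] - px, pts[:, 1] - py)
            i = int(np.argmin(dists))
            assert abs(dev) == pytest.approx(dists[i], abs=1e-3)
            assert s_proj == pytest.approx(grid[i], abs=1e-2)
            assert math.copysign(1, dev) == math.copysign(1, d)

    def test_hint_far_behind_still_converges(self, course):
        s = course.total_length * 0.75
        x, y, _, _ = course.pose(s)
        d, s_proj = course.project(x, y, s - 400.0)
        assert abs(d) < 1e-9
        assert s_proj == pytest.approx(s, abs=1e-6)

    def test_off_road_error(self, toy_course):
        x, y, h, _ = toy_course.pose(50.0)
        far = 3.5 * 3 + 1.0
        with pytest.raises(OffRoadError):
            lateral_deviation(toy_course, x - far * math.sin(h), y + far * math.cos(h), 50.0)
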