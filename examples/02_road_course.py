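"""Procedural road courses.

Generates a seeded random course — straights of 50-150 m alternating with
bends whose curvature magnitude is uniform in [1/180, 1/80] 1/m and whose
turning direction alternates — then queries poses and lateral deviations.
"""

from lanecue import generate_course

course = generate_course(seed=7)
print(course)
print(f"{'kind':>9} {'start_s (m)':>12} {'length (m)':>11} {'radius (m)':>11}")
for seg in course.segments[:8]:
    radius = "inf" if seg.curvature == 0 else f"{1 / abs(seg.curvature):11.1f}"
    side = "" if seg.curvature == 0 else (" (left)" if seg.curvature > 0 else " (right)")
    print(f"{seg.kind:>9} {seg.start_s:12.1f} {seg.length:11.1f} {radius:>11}{side}")

# pose query and the round trip through lateral projection
s = 420.0
x, y, heading, kappa = course.pose(s)
print(f"\npose at s={s:.0f} m: x={x:.1f}, y={y:.1f}, heading={heading:.3f} rad, "
      f"curvature={kappa:.4f} 1/m")
import math

d = 0.8  # displace 0.8 m to the left of the lane centre
dev, s_proj = course.project(x - d * math.sin(heading), y + d * math.cos(heading), s)
print(f"point 0.8 m left of centre projects back to s={s_proj:.1f} m "
      f"with deviation {dev:+.3f} m (positive = left)")
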