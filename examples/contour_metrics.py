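"""Measure a single luminal cross-section: A, B, C and the irregularity.

Builds an elliptical 15 x 10 mm contour (a mildly non-circular lumen),
measures its perimeter A, its mean through-center diameter B over 180
one-degree steps, and the circularity ratio C = A / (pi * B).  A perfect
circle gives C = 1; the ellipse's elongation alone already yields C ~ 1.04,
i.e. a per-slice irregularity contribution of ~4.1.
"""

import numpy as np

from shagginess import Contour, circularity_ratio, diameter_fan, perimeter, slice_irregularity

# ellipse sampled uniformly in arc length, 720 vertices
t = np.linspace(0.0, 2 * np.pi, 200_001)
x, y = 15.0 * np.cos(t), 10.0 * np.sin(t)
s = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
si = np.linspace(0.0, s[-1], 720, endpoint=False)
contour = Contour(np.column_stack([np.interp(si, s, x), np.interp(si, s, y)]))

A = perimeter(contour)
fan = diameter_fan(contour, center=(0.0, 0.0), n_angles=180)
C = circularity_ratio(A, fan.mean_diameter)

print(f"contour length        A = {A:.3f} mm")
print(f"mean diameter         B = {fan.mean_diameter:.3f} mm  (over {fan.n_angles} angles)")
print(f"circularity ratio     C = A/(pi*B) = {C:.5f}")
print(f"slice irregularity    (C-1)*100 = {slice_irregularity(C):.3f}")
print()
print("A circle of diameter B would have length pi*B =", f"{np.pi * fan.mean_diameter:.3f} mm;")
print("the excess contour length over that circle is what the score senses.")
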