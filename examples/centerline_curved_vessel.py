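"""Extract the central luminal line of a curved vessel and check its accuracy.

Builds a 90-degree arc tube (bend radius 60 mm, lumen radius 10 mm) — a
stand-in for the aortic arch-to-descending segment — extracts the
centerline by medialness-weighted minimum-cost path between the two end
landmarks, and reports how close it lands to the true axis.
"""

import numpy as np

from shagginess import CrossSectionSpec, PhantomSpec, extract_centerline, rasterize_phantom
from shagginess.validation import centerline_rms_voxels

spec = PhantomSpec(
    path="arc",
    length_mm=60.0 * np.pi / 2,   # quarter turn of a 60 mm bend
    bend_radius_mm=60.0,
    section=CrossSectionSpec(family="circle", R=10.0),
)
phantom = rasterize_phantom(spec)

proximal, distal = phantom.seed_points()
centerline = extract_centerline(phantom.volume, proximal, distal)

rms = centerline_rms_voxels(phantom, centerline)
print(f"true arc length          : {spec.length_mm:.1f} mm")
print(f"extracted centerline     : {len(centerline)} points, {centerline.length:.1f} mm")
print(f"RMS distance to true axis: {rms:.3f} voxels (1 voxel = 1 mm)")
print()
print("Sub-voxel agreement means the perpendicular slice planes are placed")
print("accurately enough for the per-slice diameters to be trusted.")
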