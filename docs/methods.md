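# Methods

## Model

The shagginess score treats luminal irregularity as excess boundary length.
For a cross-section perpendicular to the central luminal line, let A be the
length of the traced luminal contour and B the mean of 180 through-center
diameters (one per degree; each diameter is the sum of the two opposed
ray distances from the center to the boundary). The circularity ratio

    C = A / (π · B)

is 1 for a circle and strictly greater for any non-circular section whose
diameters are measured through an interior point (a consequence of Cauchy's
mean-width identity: perimeter = π × mean caliper width, and the
through-center chord never exceeds the caliper width in its direction).
The score of a segment is the unweighted mean of (C − 1) × 100 over
perpendicular slices placed at a regular arc-length spacing between two
user-chosen landmarks; regular spacing makes equal slice weights equivalent
to arc-length weighting. Endpoints of the scored range are inclusive.

C is dimensionless and invariant under uniform scaling, so the score
responds to shape, not caliber. It conflates elongation (ellipticity) with
fine-scale irregularity: a smooth 15×10 mm ellipse already contributes
≈ 4.1. This is inherent to the index, not an implementation artifact.

## Pipeline and parameters

| stage | parameter | default | rationale |
|---|---|---|---|
| centerline | medialness cost | 1/(1+DT)² per mm | strongly prefers medial voxels; DT = Euclidean distance transform (mm) |
| centerline | smoothing window | 10 mm | removes voxel zig-zag, preserves aortic-scale curvature |
| centerline | slice spacing | 1.5 mm | middle of the conventional 1.2–1.7 mm reconstruction band |
| centerline | centroid refinement | 2 iterations | recenters the voxel-quantized path to the sub-voxel cross-sectional centroid; an off-center fan biases B low by ≈ d²/(4R²) |
| MPR | in-plane window | 80×80 mm, 0.5 mm | covers any aorta; 0.25 mm used for oracle-grade comparisons |
| MPR | interpolation | quintic B-spline | trilinear attenuates ~10 mm-wavelength boundary undulations by several percent; spline coefficients are cached per volume (`order=1` gives trilinear) |
| contour | iso-level | 0.5 (mask), ≥ HU threshold for CT | the mask path is the tested reference; the lumen criterion of clinical workstations is undocumented |
| contour | vertices | 720 | fixed vertex count removes the resolution dependence of polygonal perimeter ("coastline effect") |
| contour | low-pass cutoff | 2 mm | Fourier cutoff on x(s), y(s): removes voxel-raster wiggle that inflates A quadratically, passes ≥ 9 mm anatomy essentially unattenuated; a sliding-window smoother at comparable suppression measurably attenuates real lobes |
| fan | angles | 180 | one diameter per degree over the half-circle, paired rays |
| fan | chord policy | first crossing | protruding material narrows the effective lumen, which is what the score should sense; `farthest` is available |
| score | π | machine precision | the two-decimal constant 3.14 seen in printed formulas changes C by ≈ 0.05%; `printed_pi` reproduces it |

Every parameter above is recorded verbatim in the emitted result, so a
score is always accompanied by the settings that produced it.

### Robustness policy

Slice-level failures never abort a segment. A slice with no traceable
contour around the centerline point is flagged `no_contour` and excluded
from the mean; a slice whose centerline point falls outside the traced
contour (crescent or strongly eccentric lumens) is measured through the
contour centroid, kept in the mean, and flagged `centroid_fallback` so the
substitution is auditable in the per-slice table.

## Synthetic phantoms

Phantoms are tubes swept along straight, circular-arc or helical paths with
star-shaped polar cross-sections: circle, ellipse, lobed
r(θ) = R(1 + ε sin kθ), and circles with Gaussian protrusions ("bumped").
Star shape guarantees the through-center chord at angle θ is exactly
r(θ) + r(θ+π), so A, B and C reduce to 1D quadratures (`analytic_C`,
evaluated to ~1e-10) — an oracle that is independent of the image pipeline.

Voxelization assigns each voxel the value of an integrated-Gaussian edge
profile of its signed distance to the tube surface (σ = 0.7 × voxel size),
emulating the scanner's edge-spread: boundary voxels hold fractional
values, and the 0.5 iso-level lies exactly on the true surface regardless
of σ. A hard `binary` mode and an explicit blur-then-threshold mode exist
for robustness experiments. Default study conditions for validation are
1 mm isotropic voxels, 150 mm tubes of aortic caliber (R = 10–12.5 mm),
slice spacing 1.5 mm.

What the phantoms do **not** emulate: CT noise and streak/motion artifacts,
contrast-timing inhomogeneity, wall thrombus with intermediate attenuation,
branch ostia opening the contour, and non-star-shaped (overhanging)
ulcerations. Passing the phantom suite therefore demonstrates geometric
fidelity of the measurement chain, not robustness to every clinical
confounder; on real data the flags and the settings record are the audit
trail.

## Numerical behavior and verified accuracy

All quantities below are computed by the test suite and
`scripts/acceptance.py` at 1 mm voxels, 0.25 mm in-plane sampling:

* circular tube: |score| < 0.003 (band: < 0.5);
* ellipse 15×10: within ~0.1% of the quadrature truth (band: 5%);
* lobed ε ∈ {0.02, 0.05, 0.10}, k = 6: within 2% of truth, strictly
  increasing in ε; the worst case (ε = 0.05, ≈ −1.7%) is dominated by
  aliasing of the 0.7 mm edge profile at 1 mm sampling — information lost
  in the voxel data, not recoverable by interpolation;
* 30° oblique rotation and uniform ×2 scaling move the lobed score by
  < 0.05% relative;
* centerline RMS vs true axis: ≈ 0 (straight), ≈ 0.22 voxels (90° arc);
* fan and perimeter agree with an exhaustive per-edge brute-force oracle to
  < 1e-6 relative on random star-shaped polygons;
* repeated runs are byte-identical (no unseeded randomness anywhere in the
  scoring path).

Degenerate inputs are rejected with typed errors: contours with < 3 points,
zero area or self-intersection; seeds outside the mask or in disconnected
components (reporting both component sizes); landmarks > 20 mm off the
centerline (reporting the distance); slice spacing outside [0.5, 5] mm
(with a warning outside the conventional 1.2–1.7 mm band). Rays hitting a
polygon vertex exactly are registered on at least one incident edge via an
interval tolerance.

## Design choices that were genuinely open

* **Fan center.** "Through the central luminal line" leaves the center
  definition to the centerline; after centroid refinement the fan center is
  the cross-sectional centroid. For asymmetric (bumped) sections this
  differs slightly from the polar origin the analytic oracle integrates
  about — one reason the seeded bumped-tube report pair is looser than the
  symmetric families, alongside attenuation of bumps whose angular width
  approaches the voxel size.
* **Non-convex chords.** First (nearest) crossing per ray by default:
  protruding atheroma should narrow the measured diameter and thus raise C.
* **Flag semantics.** Only `no_contour`/`excluded` drop a slice;
  `centroid_fallback` does not, because discarding every eccentric slice
  would bias long-segment scores on tortuous vessels.
* **Contour smoothing.** A sharp spectral cutoff rather than a kernel
  smoother, because perimeter is quadratically sensitive to residual
  high-frequency wiggle while any kernel wide enough to suppress it also
  attenuates genuine ~10 mm undulations.

## Limitations

Absolute scores are pipeline-dependent: contour tracing, smoothing and
interpolation choices shift the zero-offset and the gain on fine-scale
irregularity, and commercial workstations do not publish theirs. Scores
are therefore comparable within one settings record, not across pipelines.
Features below ~2× the voxel size are attenuated by sampling alone. The
centerline is a single path: bifurcation-aware trees and branch-ostium
exclusion are out of scope, as is lumen segmentation from unenhanced or
poorly enhanced CT beyond a simple HU threshold.
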