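# shagginess

Quantitative scoring of aortic luminal irregularity ("shagginess") from 3D
CT-derived lumen geometry.

## The problem

A *shaggy aorta* — extensive atheromatous degeneration with diffuse
ulceration and unstable, protruding plaque — carries a high risk of
atheroembolism (to kidneys, bowel, toes) during endovascular procedures and
is associated with worse long-term outcome. In practice it is usually graded
visually, which is subjective and slow. This package implements a
semi-automatic, geometry-based index of luminal irregularity computed from a
contrast-enhanced CT lumen segmentation: ulcerated or protruding atheroma
elongates the luminal contour seen in a cross-section perpendicular to the
vessel axis, and the excess of that contour length over the circumference of
an equivalent circle is a direct measure of irregularity.

## The score

For a vessel segment delimited by two user-chosen landmarks:

1. A **central luminal line** is extracted from the lumen mask
   (medialness-weighted minimum-cost path between the landmarks, smoothed,
   recentered to the cross-sectional centroid, and resampled at a regular
   slice spacing, default 1.5 mm).
2. At each centerline sample an **MPR plane** perpendicular to the
   centerline is reconstructed and the luminal contour is traced
   (sub-pixel iso-contour, resampled to 720 vertices).
3. Per slice:
   * **A** — the contour length (mm);
   * **B** — the mean of 180 **through-center diameters**, one per degree,
     each the chord through the centerline point (mm);
   * **C = A / (π·B)** — the ratio of the contour length to the
     circumference of a perfect circle of diameter B.
4. The **shagginess score** of the segment is the mean of **(C − 1) × 100**
   over the slices between the landmarks.

A perfectly circular lumen scores 0; C is scale-free, so the score reflects
shape irregularity, not vessel caliber. Because no patient data ships with
(or is needed by) this package, validation is against **synthetic vessel
phantoms** whose per-slice C is known in closed quadrature form.

## Worked example

```bash
python examples/phantom_pipeline.py
```

```text
phantom volume: 35x35x185 voxels at 1 mm
pipeline shagginess score : 8.4097  (mean over 83 slices)
analytic ground truth     : 8.4868
relative error            : -0.91%
```

The phantom is a tube with lobed cross-section r(θ) = 10·(1 + 0.1·sin 6θ) mm
— a strongly undulating lumen. The pipeline recovers the analytic
irregularity to within ~1% from a 1 mm-voxel rasterization; a circular tube
on the same pipeline scores ≈ 0.001. `examples/contour_metrics.py` shows the
per-slice quantities on a single elliptical section (A = 79.327 mm,
B = 24.245 mm, C = 1.04146), and `examples/centerline_curved_vessel.py`
demonstrates sub-voxel centerline recovery on a curved vessel.

## Command line

```bash
# synthesize a phantom volume + landmarks
shagginess phantom spec.json --out-volume tube.nii.gz --out-landmarks lm.json

# score a lumen mask (NIfTI or DICOM directory) between two landmarks
shagginess score tube.nii.gz --landmarks lm.json --out-csv slices.csv

# raw CT instead of a mask: threshold the contrast-filled lumen first
shagginess score ct.nii.gz --kind ct --hu-threshold 200 --landmarks lm.json

# per-slice table to stdout; built-in phantom-vs-oracle check
shagginess slices tube.nii.gz --landmarks lm.json
shagginess validate
```

Landmarks are world-mm points (JSON `{"proximal": [...], "distal": [...]}`
or `--proximal x,y,z --distal x,y,z`); an explicit arc-length range
`--proximal-mm/--distal-mm` can restrict the scored segment. Results are a
JSON record (score, slice count, full settings) and a per-slice CSV
(`s_mm,A_mm,B_mm,C,irregularity,flags`).

## Scope and caveats

The package scores luminal geometry only: no wall/outer-boundary metrics,
no calcification scoring, no branch-ostium handling (slices whose contour
cannot be traced are flagged and excluded, and the scored range is under
user control). Absolute scores depend on contouring and smoothing choices,
which commercial workstations do not document; comparisons should therefore
be made within one pipeline and settings record. See `docs/methods.md` for
the model, parameter defaults, and known limitations.
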