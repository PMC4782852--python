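"""Volume I/O, lumen thresholding, run configuration and the end-to-end
pipeline.

The world coordinate frame is the volume affine's (NIfTI RAS mm); DICOM
series are converted to the same convention on read, so landmarks given in
mm are portable between the two inputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .centerline import VolumeGrid, extract_centerline, smooth_and_resample
from .errors import PipelineError, SeedError, ShagginessError
from .mpr import plane_frames, refine_centerline
from .scoring import (
    MeasureSettings,
    ShagginessResult,
    landmarks_to_arclength,
    measure_slice,
    shagginess_score,
)

__all__ = [
    "RunConfig",
    "read_volume",
    "write_volume",
    "threshold_lumen",
    "run_pipeline",
]

log = logging.getLogger("shagginess")


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI file (.nii/.nii.gz) or a DICOM series directory.

    DICOM slices are sorted by their position along the slice normal; the
    LPS patient frame is converted to RAS and rescale slope/intercept are
    applied, so values are Hounsfield units for CT series.  Inconsistent
    inter-slice spacing raises an error naming the offending slices.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if path.is_dir():
        return _read_dicom_series(path)
    img = nib.load(str(path))
    voxels = np.asanyarray(img.dataobj).astype(np.float32)
    if voxels.ndim == 4 and voxels.shape[3] == 1:
        voxels = voxels[..., 0]
    return VolumeGrid(voxels, np.asarray(img.affine, dtype=float))


def _read_dicom_series(directory: Path) -> VolumeGrid:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() in ("", ".dcm"))
    datasets = []
    for p in files:
        try:
            datasets.append((p.name, pydicom.dcmread(str(p))))
        except Exception:
            continue
    if not datasets:
        raise ShagginessError(f"no readable DICOM slices in {directory}")

    iop = np.asarray(datasets[0][1].ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    keyed = sorted(
        datasets,
        key=lambda nd: float(np.dot(np.asarray(nd[1].ImagePositionPatient, float), normal)),
    )
    names = [n for n, _ in keyed]
    zs = np.array([float(np.dot(np.asarray(d.ImagePositionPatient, float), normal)) for _, d in keyed])
    if len(zs) < 2:
        raise ShagginessError("DICOM series needs at least 2 slices")
    steps = np.diff(zs)
    if np.any(np.abs(steps - steps.mean()) > 1e-3 * max(1.0, abs(steps.mean()))):
        bad = [names[i + 1] for i in np.nonzero(np.abs(steps - steps.mean()) > 1e-3)[0]]
        raise ShagginessError(f"inconsistent DICOM slice spacing at: {', '.join(bad)}")

    ds0 = keyed[0][1]
    pr, pc = (float(x) for x in ds0.PixelSpacing)
    slope = float(getattr(ds0, "RescaleSlope", 1.0))
    intercept = float(getattr(ds0, "RescaleIntercept", 0.0))
    stack = np.stack([d.pixel_array for _, d in keyed], axis=-1).astype(np.float32)
    stack = stack * slope + intercept
    # pixel_array is (row, col); build affine in LPS then flip to RAS
    affine = np.eye(4)
    affine[:3, 0] = col_dir * pc      # axis 0 of our array order below: columns
    affine[:3, 1] = row_dir * pr
    affine[:3, 2] = normal * steps.mean()
    affine[:3, 3] = np.asarray(ds0.ImagePositionPatient, dtype=float)
    voxels = np.transpose(stack, (1, 0, 2))  # (col, row, slice)
    lps_to_ras = np.diag([-1.0, -1.0, 1.0, 1.0])
    return VolumeGrid(voxels, lps_to_ras @ affine)


def write_volume(volume: VolumeGrid, path) -> None:
    """Write a volume as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32), volume.affine), str(path))


def threshold_lumen(ct: VolumeGrid, hu_threshold: float = 200.0, seed_world=None) -> VolumeGrid:
    """Binary lumen mask from attenuation values: ``value >= threshold``,
    keeping the connected component containing the proximal seed (or the
    largest component if no seed is given).  Raises on an empty result."""
    binary = ct.voxels >= hu_threshold
    if not binary.any():
        raise ShagginessError(f"threshold {hu_threshold} leaves an empty mask")
    labels, n = ndimage.label(binary)
    if seed_world is not None:
        idx = np.round(ct.world_to_voxel(np.asarray(seed_world, float))).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(ct.shape)) or labels[tuple(idx)] == 0:
            raise SeedError(f"seed {tuple(np.asarray(seed_world, float))} not inside any thresholded component")
        keep = labels[tuple(idx)]
    else:
        keep = int(np.argmax(np.bincount(labels.ravel())[1:])) + 1
    return VolumeGrid((labels == keep).astype(np.float32), ct.affine)


@dataclass(frozen=True)
class RunConfig:
    """Full, reproducible parameter record of one scoring run.

    Every parameter that can affect the score is recorded verbatim in the
    emitted :class:`ShagginessResult` settings block.
    """

    input_path: str = ""
    input_kind: str = "mask"            # "mask" | "ct"
    hu_threshold: float = 200.0
    landmark_proximal: tuple = ()       # world mm; doubles as centerline seed
    landmark_distal: tuple = ()
    s_prox_mm: float | None = None      # optional explicit arc-length range
    s_dist_mm: float | None = None
    slice_spacing_mm: float = 1.5       # regular perpendicular slice thickness
    centerline_smooth_mm: float = 10.0
    refine_iterations: int = 2          # sub-voxel centroid recentering passes
    n_angles: int = 180
    contour_vertices: int = 720
    grid_spacing_mm: float = 0.5
    half_extent_mm: float = 40.0
    contour_smooth_mm: float = 2.0
    interp_order: int = 5
    level: float = 0.5
    chord_policy: str = "first"
    printed_pi: bool = False            # True -> C = A/(3.14 B) as printed
    out_json: str = ""
    out_csv: str = ""
    seed: int = 0

    def measure_settings(self) -> MeasureSettings:
        return MeasureSettings(
            level=self.level,
            half_extent_mm=self.half_extent_mm,
            grid_spacing_mm=self.grid_spacing_mm,
            n_angles=self.n_angles,
            contour_vertices=self.contour_vertices,
            contour_smooth_mm=self.contour_smooth_mm,
            interp_order=self.interp_order,
            chord_policy=self.chord_policy,
            pi_value=3.14 if self.printed_pi else float(np.pi),
        )


def _stage(name):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s ...", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s done in %.2f s", name, dt)
            else:
                log.error("stage %s failed after %.2f s: %s", name, dt, exc)
            return False

    return _Timer()


def run_pipeline(config: RunConfig, volume: VolumeGrid | None = None) -> ShagginessResult:
    """Execute the full scoring pipeline.

    read volume -> (threshold if CT) -> centerline between the landmarks ->
    regular resampling at the slice spacing -> perpendicular frames ->
    per-slice measurement -> landmark-delimited mean.  Stage failures are
    re-raised as :class:`PipelineError` tagged with the stage name.  A
    pre-loaded ``volume`` may be passed to skip the read stage (library
    use); outputs are written only when paths are configured.
    """
    if not (1.2 <= config.slice_spacing_mm <= 1.7):
        log.warning(
            "slice spacing %.2f mm is outside the conventional 1.2-1.7 mm band",
            config.slice_spacing_mm,
        )
    if len(config.landmark_proximal) != 3 or len(config.landmark_distal) != 3:
        raise PipelineError("landmarks", "both proximal and distal landmarks (world mm) are required")

    try:
        with _stage("read"):
            if volume is None:
                volume = read_volume(config.input_path)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("read", e) from e

    prox = np.asarray(config.landmark_proximal, dtype=float)
    dist = np.asarray(config.landmark_distal, dtype=float)

    try:
        if config.input_kind == "ct":
            with _stage("threshold"):
                mask = threshold_lumen(volume, config.hu_threshold, seed_world=prox)
        elif config.input_kind == "mask":
            mask = volume
        else:
            raise ValueError(f"unknown input kind {config.input_kind!r}")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("threshold", e) from e

    try:
        with _stage("centerline"):
            raw = extract_centerline(mask, prox, dist, smooth_window_mm=config.centerline_smooth_mm)
            centerline = smooth_and_resample(
                raw, spacing_mm=config.slice_spacing_mm, smooth_window_mm=config.centerline_smooth_mm
            )
            if config.refine_iterations > 0:
                centerline = refine_centerline(
                    mask, centerline,
                    level=config.level,
                    grid_spacing_mm=config.grid_spacing_mm,
                    half_extent_mm=config.half_extent_mm,
                    iterations=config.refine_iterations,
                    order=min(3, config.interp_order),
                )
    except Exception as e:
        raise PipelineError("centerline", e) from e

    try:
        with _stage("frames"):
            frames = plane_frames(centerline)
    except Exception as e:
        raise PipelineError("frames", e) from e

    settings = config.measure_settings()
    try:
        with _stage("measure"):
            measurements = [
                measure_slice(mask, frame, s, settings)
                for frame, s in zip(frames, centerline.arclength)
            ]
    except Exception as e:
        raise PipelineError("measure", e) from e

    try:
        with _stage("score"):
            if config.s_prox_mm is not None and config.s_dist_mm is not None:
                s_prox, s_dist = float(config.s_prox_mm), float(config.s_dist_mm)
                if s_prox >= s_dist:
                    raise ValueError(f"s_prox ({s_prox}) must be < s_dist ({s_dist})")
            else:
                s_prox, s_dist = landmarks_to_arclength(centerline, prox, dist)
            result = shagginess_score(measurements, s_prox, s_dist, settings=asdict(config))
    except Exception as e:
        raise PipelineError("score", e) from e

    if config.out_json:
        Path(config.out_json).write_text(json.dumps(result.to_dict(), indent=2) + "\n")
    if config.out_csv:
        result.to_frame().to_csv(config.out_csv, index=False)
    return result
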