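"""Convenience harness: run the full image pipeline on a phantom.

Shared by the CLI ``validate`` verb, the test suite and the acceptance
script so that "pipeline score on phantom X" always means exactly the same
computation.
"""

from __future__ import annotations

import numpy as np

from .io import RunConfig, run_pipeline
from .phantom import Phantom, PhantomSpec, rasterize_phantom
from .scoring import ShagginessResult


def score_phantom(
    phantom: Phantom,
    grid_spacing_mm: float = 0.5,
    slice_spacing_mm: float = 1.5,
    seed_inset_mm: float = 3.0,
    range_inset_mm: float = 10.0,
    **config_overrides,
) -> ShagginessResult:
    """Run the standard scoring pipeline on a rasterized phantom.

    The phantom's own tube-end points (inset ``seed_inset_mm`` from the
    caps) serve as the centerline seeds, and the scored arc-length range is
    inset a further ``range_inset_mm`` from each end so end-cap slices
    (whose perpendicular plane clips the flat cap) never enter the mean —
    mirroring how landmarks bracket an interior aortic segment.
    """
    prox, dist = phantom.seed_points(seed_inset_mm)
    config = RunConfig(
        input_kind="mask",
        landmark_proximal=tuple(prox),
        landmark_distal=tuple(dist),
        slice_spacing_mm=slice_spacing_mm,
        grid_spacing_mm=grid_spacing_mm,
        half_extent_mm=min(40.0, phantom.spec.section.max_radius + 12.0),
        **config_overrides,
    )
    result = run_pipeline(config, volume=phantom.volume)
    if range_inset_mm > 0:
        lo, hi = result.s_range
        from .scoring import shagginess_score

        result = shagginess_score(
            result.slices, lo + range_inset_mm, hi - range_inset_mm, settings=result.settings
        )
    return result


def pipeline_score_on_phantom(spec: PhantomSpec, **kwargs) -> float:
    """Rasterize ``spec`` and return the pipeline's shagginess score."""
    return float(score_phantom(rasterize_phantom(spec), **kwargs).score)


def centerline_rms_voxels(phantom: Phantom, centerline) -> float:
    """RMS distance (in voxels) from extracted centerline points to the
    true axis, evaluated away from the tube ends where the medial path
    legitimately terminates at the seeds."""
    spec = phantom.spec
    s_dense = np.arange(0.0, spec.length_mm + 1e-9, 0.1)
    truth = spec.path_points(s_dense)
    from scipy.spatial import cKDTree

    tree = cKDTree(truth)
    s_lo, s_hi = 5.0, spec.length_mm - 5.0
    pts = centerline.points
    # keep points whose nearest true-axis arc length is interior
    dist, idx = tree.query(pts)
    keep = (s_dense[idx] >= s_lo) & (s_dense[idx] <= s_hi)
    d = dist[keep]
    return float(np.sqrt(np.mean(d**2)) / phantom.volume.spacing.max())
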