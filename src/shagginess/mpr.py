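"""Multiplanar reconstruction: planes perpendicular to the centerline.

Each centerline sample gets a :class:`PlaneFrame` whose normal is the local
tangent and whose in-plane axes are propagated by rotation-minimizing
(double-reflection) parallel transport, so the in-plane coordinate system
does not spin arbitrarily between consecutive slices.  The volume is
resampled on each plane by B-spline interpolation (quintic in the scoring
pipeline; trilinear available) and the luminal contour is traced as a
sub-pixel marching-squares iso-line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from shapely.geometry import Point, Polygon

from .centerline import Centerline, VolumeGrid
from .contour import Contour, resample_contour
from .errors import NoContourError, ShagginessError

__all__ = [
    "PlaneFrame",
    "plane_frames",
    "sample_plane",
    "extract_lumen_contour",
    "refine_centerline",
]


@dataclass(frozen=True)
class PlaneFrame:
    """Right-handed orthonormal frame {u_axis, v_axis, normal} anchored at a
    centerline sample (world mm)."""

    origin: np.ndarray
    normal: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray

    def __post_init__(self):
        for name in ("origin", "normal", "u_axis", "v_axis"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            v.setflags(write=False)
            object.__setattr__(self, name, v)

    def plane_to_world(self, uv: np.ndarray) -> np.ndarray:
        """Map in-plane (u, v) mm offsets to world coordinates."""
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        return self.origin + uv[:, :1] * self.u_axis + uv[:, 1:2] * self.v_axis


def plane_frames(centerline: Centerline) -> list[PlaneFrame]:
    """One perpendicular frame per centerline point.

    Normals are the centerline tangents; u/v axes follow the
    double-reflection rotation-minimizing frame so successive u axes rotate
    only as much as the tangent forces them to.
    """
    if len(centerline) < 2:
        raise ShagginessError("plane frames need a centerline with >= 2 points")
    pts = centerline.points
    tans = centerline.tangents
    norms = np.linalg.norm(tans, axis=1)
    if np.any(norms < 1e-12):
        raise ShagginessError("degenerate (zero) tangent on centerline")
    tans = tans / norms[:, None]

    # initial u: world axis least aligned with the first tangent, orthogonalized
    t0 = tans[0]
    seed = np.eye(3)[np.argmin(np.abs(t0))]
    u = seed - np.dot(seed, t0) * t0
    u /= np.linalg.norm(u)

    frames = [PlaneFrame(pts[0], t0, u, np.cross(t0, u))]
    for i in range(len(pts) - 1):
        # double-reflection transport of u from sample i to i+1
        v1 = pts[i + 1] - pts[i]
        c1 = np.dot(v1, v1)
        if c1 < 1e-24:
            ui1 = frames[-1].u_axis.copy()
        else:
            rl = frames[-1].u_axis - (2.0 / c1) * np.dot(v1, frames[-1].u_axis) * v1
            tl = tans[i] - (2.0 / c1) * np.dot(v1, tans[i]) * v1
            v2 = tans[i + 1] - tl
            c2 = np.dot(v2, v2)
            ui1 = rl if c2 < 1e-24 else rl - (2.0 / c2) * np.dot(v2, rl) * v2
        ui1 = ui1 - np.dot(ui1, tans[i + 1]) * tans[i + 1]
        ui1 /= np.linalg.norm(ui1)
        frames.append(PlaneFrame(pts[i + 1], tans[i + 1], ui1, np.cross(tans[i + 1], ui1)))
    return frames


def _spline_coefficients(volume: VolumeGrid, order: int) -> np.ndarray:
    """Cubic B-spline coefficients of the volume, computed once per volume
    and cached on the (frozen) instance."""
    cache = getattr(volume, "_spline_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(volume, "_spline_cache", cache)
    if order not in cache:
        cache[order] = ndimage.spline_filter(
            volume.voxels.astype(float), order=order, mode="constant"
        )
    return cache[order]


def sample_plane(
    volume: VolumeGrid,
    frame: PlaneFrame,
    half_extent_mm: float = 40.0,
    grid_spacing_mm: float = 0.5,
    order: int = 3,
) -> np.ndarray:
    """Resample the volume on a square in-plane grid centered at the frame
    origin; samples outside the volume are 0.

    Interpolation is a cubic B-spline by default (``order=3``), which
    reconstructs smooth partial-volume boundaries with far less amplitude
    attenuation than trilinear; pass ``order=1`` for plain trilinear.
    Returns a 2D array ``img[j, i]`` where column ``i`` runs along
    ``u_axis`` and row ``j`` along ``v_axis``; the center pixel sits at the
    frame origin.
    """
    if grid_spacing_mm <= 0:
        raise ValueError("grid spacing must be positive")
    n = int(round(2.0 * half_extent_mm / grid_spacing_mm)) + 1
    offsets = (np.arange(n) - (n - 1) / 2.0) * grid_spacing_mm
    uu, vv = np.meshgrid(offsets, offsets)  # uu varies along columns
    world = (
        frame.origin[None, :]
        + uu.ravel()[:, None] * frame.u_axis[None, :]
        + vv.ravel()[:, None] * frame.v_axis[None, :]
    )
    vox = volume.world_to_voxel(world)
    if order > 1:
        src = _spline_coefficients(volume, order)
        img = ndimage.map_coordinates(
            src, vox.T, order=order, prefilter=False, mode="constant", cval=0.0
        )
    else:
        img = ndimage.map_coordinates(
            volume.voxels.astype(float), vox.T, order=1, mode="constant", cval=0.0
        )
    return img.reshape(n, n)


def _smooth_closed_contour(points: np.ndarray, cutoff_mm: float, perimeter_mm: float) -> np.ndarray:
    """Fourier low-pass of a closed, uniformly resampled contour.

    Harmonics of x(s), y(s) with wavelength shorter than ``cutoff_mm`` are
    removed outright.  Voxel-raster wiggle (which spuriously inflates the
    perimeter) lives at wavelengths of a few voxels, well below the
    ~10 mm-scale undulations the irregularity score is meant to sense, so a
    sharp spectral cutoff suppresses the artifact without attenuating the
    signal the way a sliding-window smoother would.
    """
    n = len(points)
    m_cut = int(np.floor(perimeter_mm / max(cutoff_mm, 1e-9)))
    if m_cut >= n // 2:
        return points
    out = np.empty_like(points)
    for i in range(2):
        coeff = np.fft.rfft(points[:, i])
        coeff[m_cut + 1 :] = 0.0
        out[:, i] = np.fft.irfft(coeff, n=n)
    return out


def refine_centerline(
    volume: VolumeGrid,
    centerline: Centerline,
    level: float = 0.5,
    grid_spacing_mm: float = 0.5,
    half_extent_mm: float = 40.0,
    iterations: int = 2,
    order: int = 3,
) -> Centerline:
    """Recenter each centerline point at the centroid of its perpendicular
    lumen cross-section.

    The graph-based centerline is quantized to voxel centers (up to ~0.7
    voxel off the true medial axis), which biases the through-center
    diameter fan low.  Iterating plane extraction -> contour centroid ->
    lateral recentering converges to the sub-voxel cross-sectional center;
    points whose contour cannot be traced are left untouched.
    """
    cl = centerline
    for _ in range(int(iterations)):
        frames = plane_frames(cl)
        pts = cl.points.copy()
        for i, frame in enumerate(frames):
            img = sample_plane(volume, frame, half_extent_mm, grid_spacing_mm, order=order)
            n = img.shape[0]
            c = ((n - 1) / 2.0, (n - 1) / 2.0)
            try:
                contour = extract_lumen_contour(
                    img, c, level=level, grid_spacing_mm=grid_spacing_mm,
                    n_vertices=180, smooth_window_mm=0.0,
                )
            except NoContourError:
                continue
            cx, cy = contour.centroid
            pts[i] = frame.origin + cx * frame.u_axis + cy * frame.v_axis
        cl = Centerline(pts)
    return cl


def extract_lumen_contour(
    plane_image: np.ndarray,
    center_px: tuple[float, float],
    level: float = 0.5,
    grid_spacing_mm: float = 0.5,
    n_vertices: int = 720,
    smooth_window_mm: float = 2.0,
) -> Contour:
    """Trace the closed iso-contour at ``level`` that encloses ``center_px``.

    ``center_px`` is given in array (row, col) coordinates.  The sub-pixel
    marching-squares contour is converted to in-plane mm (origin at the
    center pixel, x along columns/u, y along rows/v), oriented CCW,
    resampled to ``n_vertices`` equally spaced vertices and low-pass
    filtered (wavelengths below ``smooth_window_mm`` removed).  Among several closed candidates the smallest one enclosing
    the center (the tight lumen boundary) is returned.

    Raises :class:`NoContourError` when no closed contour encloses the
    center — callers use this as the per-slice exclusion flag.
    """
    img = np.asarray(plane_image, dtype=float)
    cy, cx = float(center_px[0]), float(center_px[1])
    candidates = []
    for rc in measure.find_contours(img, level):
        if len(rc) < 4 or not np.allclose(rc[0], rc[-1]):
            continue  # open contour: hits the image border
        xy = np.column_stack([rc[:-1, 1], rc[:-1, 0]])  # (x=col, y=row)
        if len(xy) < 3:
            continue
        poly = Polygon(xy)
        if poly.is_valid and poly.contains(Point(cx, cy)):
            candidates.append((poly.area, xy))
    if not candidates:
        raise NoContourError(f"no closed iso-contour at level {level} encloses pixel ({cy}, {cx})")
    _, xy = min(candidates, key=lambda t: t[0])

    mm = (xy - np.array([cx, cy])) * grid_spacing_mm
    contour = resample_contour(Contour(mm, check_simple=False), n_vertices)
    if smooth_window_mm > 0:
        per = float(np.linalg.norm(np.diff(np.vstack([contour.points, contour.points[:1]]), axis=0), axis=1).sum())
        pts = _smooth_closed_contour(contour.points, smooth_window_mm, per)
        contour = Contour(pts, check_simple=False)
    return contour
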