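"""Synthetic vessel phantoms with analytically known circularity.

A phantom is a tube swept along a parametric path (straight, circular arc
or helix) with a star-shaped polar cross-section r(theta) drawn from one of
four families:

* ``circle``   — r = R,
* ``ellipse``  — r = ab / sqrt(a^2 sin^2 + b^2 cos^2),
* ``lobed``    — r = R (1 + eps * sin(k * theta)), a smooth periodic
  undulation emulating diffuse luminal irregularity,
* ``bumped``   — a circle with Gaussian protrusions into the lumen,
  emulating discrete protruding atheroma.

Because the section is star-shaped about the centerline, the through-center
chord at angle theta is exactly r(theta) + r(theta + pi), so the perimeter
A, the mean diameter B and hence C = A/(pi*B) have closed quadrature forms
(:func:`analytic_C`) — an oracle the full image pipeline can be validated
against.

Rasterization fills a voxel grid with fractional (partial-volume)
occupancy: the signed distance to the tube surface mapped through an
integrated-Gaussian edge profile, emulating the scanner's edge-spread at
the lumen boundary (a voxel straddling the wall holds an intermediate
value, exactly as contrast CT renders it).  A strict ``binary`` mode and an
explicit Gaussian blur are also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.integrate import quad
from scipy.special import ndtr
from scipy.spatial import cKDTree

from .centerline import Centerline, VolumeGrid
from .contour import slice_irregularity
from .mpr import plane_frames

__all__ = [
    "CrossSectionSpec",
    "PhantomSpec",
    "Phantom",
    "analytic_C",
    "rasterize_phantom",
    "random_bumps",
]


@dataclass(frozen=True)
class CrossSectionSpec:
    """Star-shaped polar cross-section r(theta) about the centerline.

    ``bumps`` is a sequence of ``(angle_rad, width_rad, height_mm)``
    Gaussian protrusions into the lumen (they reduce the local radius).
    """

    family: str = "circle"
    R: float = 10.0
    a: float = 15.0
    b: float = 10.0
    epsilon: float = 0.0
    k: int = 6
    bumps: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.family not in ("circle", "ellipse", "lobed", "bumped"):
            raise ValueError(f"unknown section family {self.family!r}")
        if self.family == "lobed":
            if not 0 <= self.epsilon < 0.5:
                raise ValueError(f"lobe amplitude must satisfy 0 <= eps < 0.5, got {self.epsilon}")
            if self.k < 2:
                raise ValueError(f"lobe count k must be >= 2, got {self.k}")
        theta = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        if np.min(self.radius(theta)) <= 0:
            raise ValueError("radius function r(theta) must be positive everywhere")

    def radius(self, theta):
        """r(theta), vectorized over theta (radians, CCW from +x)."""
        theta = np.asarray(theta, dtype=float)
        if self.family == "circle":
            return np.full_like(theta, float(self.R))
        if self.family == "ellipse":
            return (self.a * self.b) / np.sqrt(
                self.a**2 * np.sin(theta) ** 2 + self.b**2 * np.cos(theta) ** 2
            )
        if self.family == "lobed":
            return self.R * (1.0 + self.epsilon * np.sin(self.k * theta))
        # bumped: Gaussian dents, angle wrapped to [-pi, pi]
        r = np.full_like(theta, float(self.R))
        for ang, width, height in self.bumps:
            d = np.angle(np.exp(1j * (theta - ang)))
            r = r - height * np.exp(-0.5 * (d / width) ** 2)
        return r

    def dradius(self, theta):
        """dr/dtheta, analytic per family."""
        theta = np.asarray(theta, dtype=float)
        if self.family == "circle":
            return np.zeros_like(theta)
        if self.family == "ellipse":
            s2, c2 = np.sin(theta) ** 2, np.cos(theta) ** 2
            g = self.a**2 * s2 + self.b**2 * c2
            dg = (self.a**2 - self.b**2) * 2 * np.sin(theta) * np.cos(theta)
            return -0.5 * self.a * self.b * dg / g**1.5
        if self.family == "lobed":
            return self.R * self.epsilon * self.k * np.cos(self.k * theta)
        dr = np.zeros_like(theta)
        for ang, width, height in self.bumps:
            d = np.angle(np.exp(1j * (theta - ang)))
            dr = dr + height * (d / width**2) * np.exp(-0.5 * (d / width) ** 2)
        return dr

    @property
    def max_radius(self) -> float:
        theta = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        return float(np.max(self.radius(theta)))


def analytic_C(section: CrossSectionSpec) -> float:
    """Ground-truth circularity ratio C = A/(pi*B) by quadrature.

    A is the arc length of the parametric boundary,
    ``integral sqrt(r^2 + r'^2) dtheta``; B is the mean through-center
    diameter, which for a star-shaped section reduces to
    ``(1/pi) * integral r dtheta``.  Both integrals are evaluated to 1e-10.
    """
    def arc(th):
        return np.sqrt(section.radius(th) ** 2 + section.dradius(th) ** 2)

    pieces = max(8, 4 * int(getattr(section, "k", 2)), 4 * len(section.bumps) or 8)
    edges = np.linspace(0.0, 2 * np.pi, pieces + 1)
    A = sum(
        quad(arc, lo, hi, epsabs=1e-11, epsrel=1e-11, limit=200)[0]
        for lo, hi in zip(edges[:-1], edges[1:])
    )
    R_mean = sum(
        quad(section.radius, lo, hi, epsabs=1e-11, epsrel=1e-11, limit=200)[0]
        for lo, hi in zip(edges[:-1], edges[1:])
    ) / (2 * np.pi)
    B = 2.0 * R_mean
    return float(A / (np.pi * B))


def random_bumps(rng, n_bumps: int, width_range=(0.15, 0.5), height_range=(0.5, 2.5)) -> tuple:
    """Draw ``n_bumps`` random Gaussian protrusions for a bumped section."""
    rng = np.random.default_rng(rng)
    angles = rng.uniform(0, 2 * np.pi, n_bumps)
    widths = rng.uniform(*width_range, n_bumps)
    heights = rng.uniform(*height_range, n_bumps)
    return tuple((float(a), float(w), float(h)) for a, w, h in zip(angles, widths, heights))


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic vessel volume.

    ``path`` selects the centerline shape: ``straight`` (along +z),
    ``arc`` (planar circular bend of radius ``bend_radius_mm``) or
    ``helix`` (radius ``helix_radius_mm``, pitch ``helix_pitch_mm`` per
    turn).  ``rotation`` optionally applies a rigid rotation to the whole
    phantom before voxelization (for pose-invariance studies).
    """

    path: str = "straight"
    length_mm: float = 150.0
    section: CrossSectionSpec = field(default_factory=CrossSectionSpec)
    voxel_spacing_mm: float = 1.0
    bend_radius_mm: float = 60.0
    helix_radius_mm: float = 30.0
    helix_pitch_mm: float = 40.0
    surface: str = "partial_volume"   # or "binary"
    edge_sigma_mm: float | None = None  # edge-spread sigma; default 0.7 * voxel
    blur_sigma_mm: float = 0.0
    margin_mm: float = 6.0
    seed: int = 0
    rotation: tuple = ()              # flattened 3x3 row-major, empty = identity

    def __post_init__(self):
        if self.path not in ("straight", "arc", "helix"):
            raise ValueError(f"unknown path {self.path!r}")
        if self.surface not in ("partial_volume", "binary"):
            raise ValueError(f"unknown surface mode {self.surface!r}")
        if self.voxel_spacing_mm <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.length_mm / self.voxel_spacing_mm < 20:
            raise ValueError("phantom must span at least 20 voxels along its length")
        if self.path == "arc" and self.length_mm > 2 * np.pi * self.bend_radius_mm:
            raise ValueError("arc length exceeds the full bend circle")

    def rotation_matrix(self) -> np.ndarray:
        if not self.rotation:
            return np.eye(3)
        M = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        return M

    def path_points(self, s):
        """Centerline position at arc length(s) ``s`` (before rotation)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if self.path == "straight":
            p = np.column_stack([np.zeros_like(s), np.zeros_like(s), s])
        elif self.path == "arc":
            phi = s / self.bend_radius_mm
            p = np.column_stack(
                [self.bend_radius_mm * np.sin(phi),
                 np.zeros_like(s),
                 self.bend_radius_mm * (1.0 - np.cos(phi))]
            )
        else:
            turn = np.hypot(2 * np.pi * self.helix_radius_mm, self.helix_pitch_mm)
            phi = 2 * np.pi * s / turn
            p = np.column_stack(
                [self.helix_radius_mm * np.cos(phi),
                 self.helix_radius_mm * np.sin(phi),
                 self.helix_pitch_mm * s / turn]
            )
        return p @ self.rotation_matrix().T

    def path_tangents(self, s):
        """Unit tangent at arc length(s) ``s``."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if self.path == "straight":
            t = np.tile([0.0, 0.0, 1.0], (len(s), 1))
        elif self.path == "arc":
            phi = s / self.bend_radius_mm
            t = np.column_stack([np.cos(phi), np.zeros_like(s), np.sin(phi)])
        else:
            turn = np.hypot(2 * np.pi * self.helix_radius_mm, self.helix_pitch_mm)
            phi = 2 * np.pi * s / turn
            w = 2 * np.pi * self.helix_radius_mm / turn
            t = np.column_stack(
                [-w * np.sin(phi), w * np.cos(phi),
                 np.full_like(s, self.helix_pitch_mm / turn)]
            )
            t /= np.linalg.norm(t, axis=1, keepdims=True)
        return t @ self.rotation_matrix().T

    def true_centerline(self, spacing_mm: float = 0.5) -> Centerline:
        s = np.arange(0.0, self.length_mm + 1e-9, spacing_mm)
        return Centerline(self.path_points(s))


@dataclass(frozen=True)
class Phantom:
    """Rasterized phantom: volume, true centerline and ground-truth table."""

    spec: PhantomSpec
    volume: VolumeGrid
    centerline: Centerline
    ground_truth: pd.DataFrame

    @property
    def analytic_score(self) -> float:
        """Ground-truth shagginess score (constant-section tube)."""
        return float(self.ground_truth["irregularity"].mean())

    def seed_points(self, inset_mm: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
        """Proximal/distal seed-cum-landmark points on the true axis, inset
        from the tube ends so they sit safely inside the foreground."""
        p = self.spec.path_points([inset_mm, self.spec.length_mm - inset_mm])
        return p[0], p[1]


def rasterize_phantom(spec: PhantomSpec, gt_spacing_mm: float = 1.5) -> Phantom:
    """Voxelize the phantom and tabulate its analytic per-slice ground truth.

    Every voxel center is projected onto the nearest point of a densely
    sampled true centerline; its in-plane polar angle (in a
    rotation-minimizing frame) and distance give the signed lateral distance
    to the tube surface, combined with the axial distance past the flat end
    caps.  Occupancy is an integrated-Gaussian edge profile of that signed
    distance (``partial_volume``; the 0.5 level sits exactly on the true
    surface) or a hard threshold (``binary``); an optional Gaussian blur
    followed by re-thresholding emulates a coarser point spread.
    Deterministic given the spec.
    """
    h = spec.voxel_spacing_mm
    dense_ds = min(0.25 * h, 0.5)
    s_dense = np.arange(0.0, spec.length_mm + 1e-9, dense_ds)
    c_pts = spec.path_points(s_dense)
    cl = Centerline(c_pts, arclength=s_dense.copy(),
                    tangents=spec.path_tangents(s_dense))
    frames = plane_frames(cl)
    u_axes = np.array([f.u_axis for f in frames])
    v_axes = np.array([f.v_axis for f in frames])
    t_axes = np.array([f.normal for f in frames])

    r_max = spec.section.max_radius
    lo = c_pts.min(axis=0) - (r_max + spec.margin_mm)
    hi = c_pts.max(axis=0) + (r_max + spec.margin_mm)
    shape = np.ceil((hi - lo) / h).astype(int) + 1
    affine = np.eye(4)
    affine[:3, :3] *= h
    affine[:3, 3] = lo

    ii = [np.arange(n) * h + o for n, o in zip(shape, lo)]
    gx, gy, gz = np.meshgrid(*ii, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    tree = cKDTree(c_pts)
    dist, idx = tree.query(centers, workers=-1)
    near = centers - c_pts[idx]
    du = np.einsum("ij,ij->i", near, u_axes[idx])
    dv = np.einsum("ij,ij->i", near, v_axes[idx])
    dn = np.einsum("ij,ij->i", near, t_axes[idx])
    theta = np.arctan2(dv, du)
    lateral = np.hypot(du, dv) - spec.section.radius(theta)
    axial = np.maximum(-(s_dense[idx] + dn), s_dense[idx] + dn - spec.length_mm)
    sd = np.maximum(lateral, axial)

    if spec.surface == "binary":
        vox = (sd <= 0).astype(np.float32)
    else:
        sigma = spec.edge_sigma_mm if spec.edge_sigma_mm is not None else 0.7 * h
        vox = ndtr(-sd / sigma).astype(np.float32)
    vox = vox.reshape(shape)
    if spec.blur_sigma_mm > 0:
        vox = ndimage.gaussian_filter(vox.astype(float), spec.blur_sigma_mm / h)
        vox = (vox >= 0.5).astype(np.float32)

    C = analytic_C(spec.section)
    s_gt = np.arange(0.0, spec.length_mm + 1e-9, gt_spacing_mm)
    truth = pd.DataFrame(
        {"s_mm": s_gt, "C": np.full_like(s_gt, C),
         "irregularity": np.full_like(s_gt, slice_irregularity(C))}
    )
    return Phantom(
        spec=spec,
        volume=VolumeGrid(vox, affine),
        centerline=spec.true_centerline(),
        ground_truth=truth,
    )
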