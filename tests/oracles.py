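"""Independent brute-force oracles used to validate the package geometry.

Deliberately naive implementations (per-edge loops, dense quadrature) that
share no code with the package: edge-by-edge perimeter summation,
exhaustive ray/segment intersection for through-center chords, and
trapezoid quadrature of parametric polar sections.
"""

from __future__ import annotations

import numpy as np


def brute_perimeter(points: np.ndarray) -> float:
    """Perimeter by explicit per-edge summation (closing edge included)."""
    total = 0.0
    n = len(points)
    for i in range(n):
        dx = points[(i + 1) % n][0] - points[i][0]
        dy = points[(i + 1) % n][1] - points[i][1]
        total += float(np.hypot(dx, dy))
    return total


def brute_ray_distance(points: np.ndarray, center, angle: float, farthest: bool = False) -> float:
    """Distance from center to the polygon boundary along one ray, by
    exhaustive segment intersection."""
    cx, cy = float(center[0]), float(center[1])
    ux, uy = np.cos(angle), np.sin(angle)
    hits = []
    n = len(points)
    for i in range(n):
        px, py = points[i]
        qx, qy = points[(i + 1) % n]
        ex, ey = qx - px, qy - py
        denom = ux * ey - uy * ex
        if abs(denom) < 1e-14:
            continue
        wx, wy = px - cx, py - cy
        t = (wx * ey - wy * ex) / denom
        s = (wx * uy - wy * ux) / denom
        if -1e-9 <= s <= 1 + 1e-9 and t > 1e-12:
            hits.append(t)
    if not hits:
        raise ValueError("ray found no boundary crossing")
    return max(hits) if farthest else min(hits)


def brute_diameters(points: np.ndarray, center, n_angles: int = 180) -> np.ndarray:
    """Through-center diameters at regular angle steps by brute force."""
    out = np.empty(n_angles)
    for i in range(n_angles):
        phi = i * np.pi / n_angles
        out[i] = brute_ray_distance(points, center, phi) + brute_ray_distance(
            points, center, phi + np.pi
        )
    return out


def polar_section_C(radius_fn, n: int = 200_001) -> float:
    """Circularity ratio of a star-shaped polar section by dense trapezoid
    quadrature of the arc-length and mean-radius integrals."""
    th = np.linspace(0.0, 2 * np.pi, n)
    r = radius_fn(th)
    dr = np.gradient(r, th)
    A = np.trapezoid(np.sqrt(r**2 + dr**2), th)
    B = np.trapezoid(r, th) / np.pi
    return float(A / (np.pi * B))


def random_star_polygon(rng: np.random.Generator, n_vertices: int = 120) -> np.ndarray:
    """A random star-shaped polygon about the origin: smooth positive polar
    radius from a short random Fourier series."""
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.full(n_vertices, 10.0)
    for m in range(1, 7):
        amp = rng.uniform(0, 1.2 / m)
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.cos(m * theta + phase)
    assert np.all(r > 0)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
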