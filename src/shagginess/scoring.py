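"""Per-slice metrology and aggregation of the shagginess score.

Every perpendicular MPR slice yields one :class:`SliceMeasurement` holding
the contour length A, the mean through-center diameter B over 180 angular
steps, the circularity ratio C = A/(pi*B) and the irregularity contribution
(C - 1) * 100.  The shagginess score of a landmark-delimited segment is the
plain arithmetic mean of the irregularity over the slices whose arc length
falls inside the segment — slices are equally weighted because they are
placed at a regular arc-length spacing.

Slice-level failures never abort a run: they become quality flags.
``no_contour`` and ``excluded`` drop the slice from the mean;
``centroid_fallback`` (fan center substituted by the contour centroid when
the centerline point falls outside the traced contour) keeps the slice but
leaves the substitution auditable in the per-slice table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .centerline import Centerline, VolumeGrid
from .contour import circularity_ratio, diameter_fan, perimeter, slice_irregularity
from .errors import CenterOutsideContourError, LandmarkError, NoContourError, ShagginessError
from .mpr import PlaneFrame, extract_lumen_contour, sample_plane

__all__ = [
    "MeasureSettings",
    "SliceMeasurement",
    "ShagginessResult",
    "measure_slice",
    "shagginess_score",
    "landmarks_to_arclength",
]

#: flags that remove a slice from the score mean
EXCLUSION_FLAGS = frozenset({"no_contour", "excluded"})


@dataclass(frozen=True)
class MeasureSettings:
    """Knobs of the per-slice measurement, recorded verbatim in results."""

    level: float = 0.5                 # iso-level for the lumen boundary
    half_extent_mm: float = 40.0       # in-plane half window, covers any aorta
    grid_spacing_mm: float = 0.5       # in-plane sample spacing
    n_angles: int = 180                # diameter fan: one step per degree
    contour_vertices: int = 720        # fixed resampling of every contour
    contour_smooth_mm: float = 2.0     # raster-artifact low-pass cutoff (min wavelength)
    interp_order: int = 5              # spline order of the MPR resampling
    chord_policy: str = "first"        # nearest boundary crossing per ray
    pi_value: float = math.pi          # 3.14 reproduces the printed-report constant


@dataclass(frozen=True)
class SliceMeasurement:
    """A, B, C and irregularity for one perpendicular slice at arc length s."""

    s: float
    A: float
    B: float
    C: float
    irregularity: float
    flags: frozenset = field(default_factory=frozenset)

    @property
    def usable(self) -> bool:
        return not (self.flags & EXCLUSION_FLAGS)


@dataclass(frozen=True)
class ShagginessResult:
    """Aggregated score with full per-slice provenance."""

    score: float
    n_slices_used: int
    s_range: tuple[float, float]
    slices: tuple[SliceMeasurement, ...]
    settings: dict

    def to_frame(self) -> pd.DataFrame:
        """Per-slice table (columns s_mm, A_mm, B_mm, C, irregularity, flags)."""
        return pd.DataFrame(
            {
                "s_mm": [m.s for m in self.slices],
                "A_mm": [m.A for m in self.slices],
                "B_mm": [m.B for m in self.slices],
                "C": [m.C for m in self.slices],
                "irregularity": [m.irregularity for m in self.slices],
                "flags": [";".join(sorted(m.flags)) for m in self.slices],
            }
        )

    def to_dict(self) -> dict:
        return {
            "score": self.score,
            "n_slices_used": self.n_slices_used,
            "s_range_mm": list(self.s_range),
            "settings": dict(self.settings),
            "n_slices_total": len(self.slices),
            "n_flagged": sum(1 for m in self.slices if m.flags),
        }


def measure_slice(
    volume: VolumeGrid,
    frame: PlaneFrame,
    s: float,
    settings: MeasureSettings = MeasureSettings(),
) -> SliceMeasurement:
    """Measure one perpendicular slice; failures become flags, not aborts.

    Pipeline: resample the plane -> trace the lumen contour -> perimeter A
    and 180-angle diameter fan B through the centerline point -> C and
    (C-1)*100.  If no contour encloses the centerline point the measurement
    carries the ``no_contour`` flag with NaN metrics; if the centerline
    point lies outside the traced contour the fan is measured through the
    contour centroid and the slice is flagged ``centroid_fallback``.
    """
    img = sample_plane(volume, frame, settings.half_extent_mm, settings.grid_spacing_mm,
                       order=settings.interp_order)
    n = img.shape[0]
    center_px = ((n - 1) / 2.0, (n - 1) / 2.0)
    flags: set[str] = set()
    try:
        contour = extract_lumen_contour(
            img,
            center_px,
            level=settings.level,
            grid_spacing_mm=settings.grid_spacing_mm,
            n_vertices=settings.contour_vertices,
            smooth_window_mm=settings.contour_smooth_mm,
        )
    except (NoContourError, ShagginessError):
        return SliceMeasurement(
            s=float(s), A=float("nan"), B=float("nan"), C=float("nan"),
            irregularity=float("nan"), flags=frozenset({"no_contour"}),
        )
    A = perimeter(contour)
    try:
        fan = diameter_fan(contour, (0.0, 0.0), settings.n_angles, settings.chord_policy)
    except CenterOutsideContourError:
        flags.add("centroid_fallback")
        fan = diameter_fan(contour, contour.centroid, settings.n_angles, settings.chord_policy)
    C = circularity_ratio(A, fan.mean_diameter, settings.pi_value)
    return SliceMeasurement(
        s=float(s), A=float(A), B=float(fan.mean_diameter), C=float(C),
        irregularity=slice_irregularity(C), flags=frozenset(flags),
    )


def shagginess_score(
    measurements,
    s_prox: float,
    s_dist: float,
    settings: dict | MeasureSettings | None = None,
) -> ShagginessResult:
    """Mean of (C - 1) * 100 over the slices in [s_prox, s_dist].

    Range endpoints are inclusive; slices carrying an exclusion flag are
    dropped from the mean but kept in the per-slice table.  Raises if the
    range contains no usable slice (the error reports the flag counts).
    """
    if not s_prox < s_dist:
        raise ValueError(f"need s_prox < s_dist, got {s_prox} >= {s_dist}")
    measurements = tuple(measurements)
    eps = 1e-9
    in_range = [m for m in measurements if s_prox - eps <= m.s <= s_dist + eps]
    used = [m for m in in_range if m.usable]
    if not used:
        counts: dict[str, int] = {}
        for m in in_range:
            for f in m.flags:
                counts[f] = counts.get(f, 0) + 1
        raise ShagginessError(
            f"no usable slice in [{s_prox}, {s_dist}] mm "
            f"({len(in_range)} slices in range, flag counts {counts})"
        )
    if settings is None:
        settings_dict: dict = {}
    elif isinstance(settings, MeasureSettings):
        settings_dict = asdict(settings)
    else:
        settings_dict = dict(settings)
    return ShagginessResult(
        score=float(np.mean([m.irregularity for m in used])),
        n_slices_used=len(used),
        s_range=(float(s_prox), float(s_dist)),
        slices=measurements,
        settings=settings_dict,
    )


def landmarks_to_arclength(
    centerline: Centerline,
    proximal_pt,
    distal_pt,
    max_distance_mm: float = 20.0,
) -> tuple[float, float]:
    """Map two world-space landmarks to arc lengths on the centerline.

    Each landmark snaps to its nearest centerline sample; the pair is
    returned ordered so ``s_prox < s_dist`` regardless of input order.
    A landmark farther than ``max_distance_mm`` from the centerline raises
    :class:`LandmarkError` reporting the offending distance.
    """
    ss = []
    for name, pt in (("proximal", proximal_pt), ("distal", distal_pt)):
        p = np.asarray(pt, dtype=float)
        d = np.linalg.norm(centerline.points - p, axis=1)
        i = int(np.argmin(d))
        if d[i] > max_distance_mm:
            raise LandmarkError(
                f"{name} landmark is {d[i]:.1f} mm from the centerline "
                f"(limit {max_distance_mm} mm)"
            )
        ss.append(float(centerline.arclength[i]))
    return (min(ss), max(ss))
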