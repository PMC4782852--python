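"""Exception hierarchy for the shagginess pipeline.

Stage functions raise these; ``measure_slice`` converts the recoverable ones
into per-slice quality flags instead of aborting a whole-segment run.
"""


class ShagginessError(Exception):
    """Base class for all package errors."""


class InvalidContourError(ShagginessError):
    """Contour violates its invariants (too few points, zero perimeter,
    self-intersection, zero area)."""


class CenterOutsideContourError(ShagginessError):
    """Requested fan center lies outside the contour polygon.

    Carries the offending center so callers can fall back to the centroid
    (and flag the slice) without re-deriving it.
    """

    def __init__(self, center, message=None):
        self.center = tuple(float(c) for c in center)
        super().__init__(message or f"fan center {self.center} lies outside the contour")


class NoContourError(ShagginessError):
    """No closed iso-contour enclosing the requested center was found.

    Mapped to the ``no_contour`` slice flag by the scoring layer.
    """


class SeedError(ShagginessError):
    """A centerline seed is outside the volume or outside the lumen mask."""


class DisconnectedSeedsError(ShagginessError):
    """Centerline seeds fall in different connected components of the mask."""

    def __init__(self, size_proximal, size_distal):
        self.size_proximal = int(size_proximal)
        self.size_distal = int(size_distal)
        super().__init__(
            "centerline seeds lie in disconnected foreground components "
            f"(sizes {self.size_proximal} and {self.size_distal} voxels)"
        )


class LandmarkError(ShagginessError):
    """Landmark too far from the centerline to map to an arc length."""


class PipelineError(ShagginessError):
    """Stage-tagged wrapper raised by run_pipeline."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
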