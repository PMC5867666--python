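"""Exception hierarchy for the drusen segmentation pipeline.

Every stage-specific failure derives from :class:`DruscanError` so callers
can catch pipeline problems without masking programming errors.
"""


class DruscanError(Exception):
    """Base class for all druscan-specific failures."""


class NoOpticDiscError(DruscanError):
    """No pixel exceeded the optic-disc intensity threshold; the image is
    unusable for ROI construction."""


class InvalidGeometryError(DruscanError):
    """A geometric construction degenerated (e.g. the disc centroid sits on
    the opposite image edge, or the seed annulus is empty)."""


class InvalidParameterError(DruscanError):
    """A filter or algorithm parameter is out of its valid range."""


class RegionOverflowError(DruscanError):
    """Region growing exceeded the allowed fraction of the image area,
    indicating a tolerance too lax to isolate vessels."""

    def __init__(self, fraction_reached: float, max_fraction: float):
        self.fraction_reached = float(fraction_reached)
        self.max_fraction = float(max_fraction)
        super().__init__(
            f"region grew to {fraction_reached:.3f} of the image "
            f"(limit {max_fraction:.3f}); tolerance is too lax"
        )


class DegenerateHistogramError(DruscanError):
    """Histogram has fewer than two occupied bins; no threshold exists."""


class EmptyRegionError(DruscanError):
    """A mask selected zero pixels where at least one is required."""


class PlacementError(DruscanError):
    """Phantom generation could not place the requested structures."""


class PipelineStageError(DruscanError):
    """Wraps a stage failure with the name of the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}': {cause}")
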