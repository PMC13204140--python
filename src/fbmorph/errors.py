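"""Exception hierarchy shared across the fbmorph modules."""


class FBMorphError(Exception):
    """Base class for all fbmorph errors."""


class MeshParseError(FBMorphError):
    """An STL file could not be parsed (truncated, malformed)."""


class EmptyInputError(FBMorphError):
    """The input contains no usable geometry or foreground."""


class DegenerateGeometryError(FBMorphError):
    """Geometry is rank-deficient or otherwise unsuitable for the operation."""


class UndefinedDescriptorError(FBMorphError):
    """A descriptor formula hit a zero denominator or invalid domain."""


class CalibrationError(FBMorphError):
    """Pixel-to-mm calibration could not be established reliably."""


class SegmentationError(FBMorphError):
    """Silhouette segmentation produced no usable foreground."""


class ContourError(FBMorphError):
    """The silhouette boundary is degenerate (too few points, zero area)."""


class CurvatureError(FBMorphError):
    """No contour window produced an acceptable osculating-circle fit."""


class AggregationError(FBMorphError):
    """Risk aggregation was attempted with zero evaluable indicators."""


class LayoutError(FBMorphError):
    """Synthetic photo layout is infeasible (shape/ruler overlap, no margin)."""


class ReportValidationError(FBMorphError):
    """A prompt or report component failed validation (e.g. empty block)."""


class TransportError(FBMorphError):
    """All configured chat-completion models failed."""

    def __init__(self, message: str, attempted_models: list[str] | None = None):
        super().__init__(message)
        self.attempted_models = attempted_models or []
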