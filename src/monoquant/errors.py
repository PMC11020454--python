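"""Exception hierarchy shared across the quantification pipelines."""


class MonoquantError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MonoquantError, ValueError):
    """A parameter violates its documented precondition."""


class SchemaError(MonoquantError, ValueError):
    """An input table/layout does not match the expected schema."""


class DegenerateImageError(MonoquantError):
    """No threshold can separate foreground from background."""


class EmptyForegroundError(MonoquantError):
    """A background mask left no foreground pixels to quantify."""


class InsufficientFieldsError(MonoquantError):
    """Fewer usable microscopy fields than the slide-summary minimum."""


class PairingError(MonoquantError):
    """Paired observations are incomplete or mismatched."""


class DegenerateTestError(MonoquantError):
    """A test statistic is undefined (e.g. zero variance of differences)."""


class GeometryError(MonoquantError):
    """Spot layout coordinates fall outside the image frame."""


class UnquantifiableAnalyteError(MonoquantError):
    """Saturation at the first exposure leaves no usable frame."""


class UndefinedRatioError(MonoquantError):
    """A fold-change denominator is zero."""


class MissingDataError(MonoquantError):
    """NaNs present where a complete matrix is required."""


class IncompletePanelError(MonoquantError):
    """A donor is missing genes required for the panel matrix."""

    def __init__(self, gaps):
        self.gaps = gaps
        super().__init__(f"incomplete panel; missing (donor, gene) pairs: {gaps}")


class DegenerateFeatureError(MonoquantError):
    """A zero-variance feature cannot be standardized."""


class InvalidReferenceError(MonoquantError):
    """The requested reference/control group or label is absent."""


class FitFailureError(MonoquantError):
    """Curve fitting failed to converge to finite parameters."""


class OutOfRangeError(MonoquantError):
    """An OD lies outside the invertible range of the standard curve."""

    def __init__(self, message, side):
        self.side = side  # "below" or "above"
        super().__init__(message)


class DesignError(MonoquantError):
    """Rank-deficient or confounded design matrix."""


class NormalizationFailureError(MonoquantError):
    """Median-of-ratios normalization is impossible (no all-nonzero gene)."""
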