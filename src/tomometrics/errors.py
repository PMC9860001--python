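"""Exception hierarchy for plan parsing and metric computation."""


class TomometricsError(Exception):
    """Base class for all package errors."""


class PlanFormatError(TomometricsError):
    """The input file is not a readable plan (wrong format / schema violation)."""


class UnsupportedPlanError(TomometricsError):
    """The file is a valid DICOM RT-Plan but carries no tomotherapy sinogram."""


class SinogramIntegrityError(TomometricsError):
    """A sinogram cell violates the fractional-open-time range [0, 1]."""


class MissingMetadataError(TomometricsError):
    """A metric was requested whose delivery metadata is absent from the plan."""


class UndefinedMetricError(TomometricsError):
    """The metric is mathematically undefined for this plan (e.g. all leaves closed)."""


class ParameterError(TomometricsError, ValueError):
    """An operation was called with out-of-range or degenerate parameters."""
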