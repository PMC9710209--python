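"""Exception hierarchy shared across the pipeline."""


class OligofluxError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(OligofluxError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateTraceError(OligofluxError):
    """A kinetic trace has no usable growth (plateau <= baseline)."""


class DegenerateControlError(OligofluxError):
    """The control condition cannot be used for normalization (<= 0 mean)."""


class DegenerateVarianceError(OligofluxError):
    """All groups have zero within-group variance; ANOVA is undefined."""


class AlignmentError(OligofluxError):
    """Two traces do not share (or cannot be interpolated onto) a time grid."""


class MissingDataError(OligofluxError):
    """A required group or column is empty."""


class NoPeakError(OligofluxError):
    """The flux profile has no interior maximum inside the search bracket."""
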