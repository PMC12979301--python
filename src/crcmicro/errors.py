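"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`CrcMicroError`, so callers can
trap pipeline failures without catching unrelated bugs.
"""


class CrcMicroError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CrcMicroError):
    """Invalid simulation or run configuration."""


class ValidationError(CrcMicroError):
    """An input value violates a documented precondition."""


class MissingDataError(ValidationError):
    """A required per-row value is missing (participants with missing
    scoring inputs are excluded upstream, never imputed)."""


class StratumTooSmallError(ValidationError):
    """A sex stratum has too few members for tertile scoring."""


class AlignmentError(CrcMicroError):
    """Sample identifiers of two inputs do not line up."""


class FormatError(CrcMicroError):
    """A file failed to parse as the expected format."""


class EmptyResultError(CrcMicroError):
    """A filter removed every sample or taxon."""


class DegenerateSampleError(CrcMicroError):
    """A sample has zero total reads where positive counts are required."""


class DegenerateTaxonError(CrcMicroError):
    """A taxon has zero variance where variation is required."""


class CollinearityError(ValidationError):
    """The model design matrix is rank deficient."""


class InsufficientDataError(ValidationError):
    """Fewer observations than model parameters."""


class NoEventsError(CrcMicroError):
    """Survival data contain no events; a hazard model cannot be fit."""


class ConvergenceError(CrcMicroError):
    """An iterative estimator failed to converge."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
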