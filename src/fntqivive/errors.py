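"""Exception hierarchy for the fenitrothion QIVIVE pipeline."""


class FntQiviveError(Exception):
    """Base class for all package errors."""


class SchemaError(FntQiviveError):
    """A configuration file is missing a required key or has the wrong shape."""


class ParameterValidationError(FntQiviveError):
    """A parameter violates its physiological or mathematical bounds."""


class DomainError(FntQiviveError, ValueError):
    """An input value is outside the mathematical domain of an operation."""


class UsageError(FntQiviveError):
    """An operation was applied to an object in the wrong state (e.g. wrong matrix)."""


class FittingError(FntQiviveError):
    """Nonlinear fitting failed to converge; carries the last iterate if available."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class DegenerateDataError(FittingError):
    """The data carry no signal the model class could fit (e.g. all-zero velocities)."""


class CensoredIC50Error(FntQiviveError):
    """The IC50 lies beyond the tested concentration range; carries the lower bound."""

    def __init__(self, message, bound):
        super().__init__(message)
        self.bound = bound


class IntegrationError(FntQiviveError):
    """The ODE solver failed or produced states violating tolerances."""


class UnreachableTargetError(FntQiviveError):
    """Reverse dosimetry target exceeds the forward map at the dose ceiling."""


class InsufficientRangeError(FntQiviveError):
    """The dose-response data do not span the requested benchmark response."""
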