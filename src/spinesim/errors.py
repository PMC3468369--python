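"""Exception hierarchy.

All package errors derive from :class:`SpinesimError` so callers can catch one
base class; the CLI maps subclasses onto exit codes (configuration errors → 2,
runtime/sampling errors → 3).
"""


class SpinesimError(Exception):
    """Base class for all spinesim errors."""


class SchemaError(SpinesimError):
    """A structured input (CSV, config file) is missing required fields."""


class ValidationError(SpinesimError):
    """A value violates a domain invariant (e.g. non-positive length)."""


class ConfigurationError(SpinesimError):
    """An experiment or model was configured with out-of-range parameters."""


class SamplingError(SpinesimError):
    """A sampling operation cannot proceed (empty or exhausted source)."""


class UndefinedValueError(SpinesimError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class ConvergenceError(SpinesimError):
    """Iterative fit failed to converge; carries the best model found so far."""

    def __init__(self, message, best=None, trajectory=None):
        super().__init__(message)
        self.best = best
        self.trajectory = trajectory


class CalibrationError(SpinesimError):
    """Moment-matching calibration could not reach its targets.

    ``achieved`` holds the best (length, head-width) kurtosis pair reached and
    ``best`` the corresponding model, so the failure is actionable.
    """

    def __init__(self, message, best=None, achieved=None):
        super().__init__(message)
        self.best = best
        self.achieved = achieved
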