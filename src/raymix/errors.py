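"""Exception hierarchy for raymix.

Validation problems (bad designs, malformed files, impossible configs)
and computation problems (failed fits, degenerate data) are kept on
separate branches so callers — in particular the CLI — can map them to
distinct exit codes.
"""


class RaymixError(Exception):
    """Base class for all package errors."""


class ValidationError(RaymixError):
    """Invalid user input: designs, files, configuration."""


class InvalidDesignError(ValidationError):
    """Dilution series or mixture ray parameters are not physically valid."""


class FormatError(ValidationError):
    """A plate CSV does not conform to the documented dialect."""


class ConfigurationError(ValidationError):
    """A run configuration or simulation scenario fails validation."""


class ComputationError(RaymixError):
    """A numerically well-posed request that could not be completed."""


class InvalidControlError(ComputationError):
    """Control absorbance is non-positive, so inhibition is undefined."""


class AmbiguityError(ComputationError):
    """Duplicate (concentration, replicate) keys in one treatment series."""


class DegenerateDataError(ComputationError):
    """Effects carry no concentration signal (all equal, all 0, or all 1)."""


class FitFailureError(ComputationError):
    """Nonlinear least squares failed to converge from every start."""


class NoFitError(ComputationError):
    """Model selection was asked to choose from an empty set of fits."""
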