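"""Exception hierarchy for umaic."""


class UmaicError(Exception):
    """Base class for all umaic errors."""


class ConfigurationError(UmaicError):
    """An arm/scenario/run configuration value is invalid; the message names the field."""


class DataValidationError(UmaicError):
    """An input table or published artifact violates its invariants."""


class InfeasibleTargetError(UmaicError):
    """A balance target lies outside the convex hull of the source covariates."""


class ConvergenceError(UmaicError):
    """An iterative solver failed to reach its tolerance."""
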