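"""Exception hierarchy shared across the package."""


class CytoCycleError(Exception):
    """Base class for all cytocycle errors."""


class ConfigurationError(CytoCycleError):
    """Invalid generator/pipeline configuration (bad occupancy, offsets, ...)."""


class StateError(CytoCycleError):
    """Operation applied to a matrix in the wrong scale state."""


class ParameterError(CytoCycleError):
    """Invalid numeric parameter (cofactor <= 0, quantile outside (0,1), ...)."""


class RuleError(CytoCycleError):
    """Canonical-rule table parse or evaluation failure."""
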