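"""Exception hierarchy shared across the package."""


class EmsOptError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(EmsOptError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidBoundsError(InvalidParameterError):
    """Lower bound is not strictly below the upper bound."""


class DegenerateDenominatorError(EmsOptError, ZeroDivisionError):
    """Bt - BA <= 0: every registered treatment bed is occupied by a boarder."""


class InsufficientDataError(EmsOptError, ValueError):
    """Too few observations for the requested fit."""


class InfiniteSNError(EmsOptError, ArithmeticError):
    """MSE is zero, so the signal-to-noise ratio is unbounded."""


class ExplicitBoundsError(EmsOptError, ValueError):
    """Observed responses are degenerate; desirability bounds must be given explicitly."""


class ConfigError(EmsOptError, ValueError):
    """A configuration file failed schema validation; message names the key path."""


class MissingArtifactError(EmsOptError, RuntimeError):
    """A pipeline stage was requested before the artifact it depends on exists."""
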