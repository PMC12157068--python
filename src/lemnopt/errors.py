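"""Exception hierarchy used across the package."""


class LemnoptError(Exception):
    """Base class for all package-specific errors."""


class DomainError(LemnoptError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ConfigurationError(LemnoptError, ValueError):
    """Parameters or configuration violate an invariant."""


class IntegrationError(LemnoptError, RuntimeError):
    """The ODE solver failed; the message carries the solver diagnostic."""


class NoFiniteLimitError(LemnoptError, ArithmeticError):
    """The density trajectory grows without bound (no loss term)."""


class DegenerateOptimumError(LemnoptError, RuntimeError):
    """An optimization objective has no positive interior maximum."""


class SingularSystemError(LemnoptError, RuntimeError):
    """A linear system (e.g. the kriging system) is singular."""


class ZeroVarianceError(LemnoptError, ValueError):
    """Observations have zero variance; a variance-ratio score is undefined."""
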