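"""Exception hierarchy shared across the package."""


class NeulagError(Exception):
    """Base class for all package-specific errors."""


class ShapeError(NeulagError, ValueError):
    """Array dimensions are inconsistent with the model specification."""


class ValidationError(NeulagError, ValueError):
    """A value violates a model invariant (e.g. a non-Hermitian coupling matrix)."""


class DivergenceError(NeulagError, ArithmeticError):
    """The integrator produced a non-finite state."""


class ConfigError(NeulagError, ValueError):
    """A configuration value or key is not recognised."""
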