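"""Exception hierarchy shared across the package."""


class TaufluxError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TaufluxError, ValueError):
    """An input value violates a documented precondition or invariant."""


class DegenerateDenominatorError(TaufluxError, ZeroDivisionError):
    """A mixing-model denominator is zero or negative (source at% <= control at%)."""


class UndefinedPoolError(TaufluxError, ZeroDivisionError):
    """A normalization base is empty (zero atoms, zero spectral counts, ...)."""


class SchemaError(TaufluxError, ValueError):
    """A tabular input does not conform to the expected schema."""


class StepSizeError(TaufluxError, RuntimeError):
    """A simulation step produced a negative pool; a smaller time step is needed."""
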