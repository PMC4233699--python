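"""Exception hierarchy shared across the package."""


class SpiraloxError(Exception):
    """Base class for all package errors."""


class ValidationError(SpiraloxError, ValueError):
    """A domain object or input table violates its invariants."""


class DomainError(SpiraloxError, ValueError):
    """A numeric argument lies outside the admissible interval."""


class SchemaError(ValidationError):
    """An input file does not conform to the documented CSV/JSON dialect."""
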