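"""Exception types shared across the pipeline."""


class LimnotteError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LimnotteError):
    """Invalid configuration; the message names the offending field."""


class DomainError(LimnotteError, ValueError):
    """Input outside the mathematical domain of an operation."""


class SchemaError(LimnotteError):
    """Tabular input does not conform to the documented CSV schema."""


class ValidationError(LimnotteError):
    """Row-level validation failure in otherwise well-formed input."""
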