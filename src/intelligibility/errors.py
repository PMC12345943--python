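"""Exception types shared across the package."""


class IntelligibilityError(Exception):
    """Base class for package errors."""


class DataCompletenessError(IntelligibilityError):
    """A stimulus is missing required listener or ASR transcripts."""

    def __init__(self, message: str, items: list | None = None):
        super().__init__(message)
        self.items = items or []


class SchemaError(IntelligibilityError):
    """An input table violates the documented schema."""


class ConfigError(IntelligibilityError):
    """Invalid configuration or simulation parameters."""


class DegenerateInputError(IntelligibilityError):
    """Input with no usable variation (e.g. zero variance) for a statistic."""
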