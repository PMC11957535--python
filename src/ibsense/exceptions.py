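"""Exception types shared across the pipeline."""


class InsufficientDataError(ValueError):
    """Raised when an estimate is requested from too little data."""


class SequencingError(RuntimeError):
    """Raised when trial ordering rules are violated (e.g. async before any sync)."""


class ConfigurationError(ValueError):
    """Raised for invalid or inconsistent run configuration."""


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined for the given data (e.g. zero variance)."""


class SchemaError(ValueError):
    """Raised when a file does not match the expected column schema."""
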