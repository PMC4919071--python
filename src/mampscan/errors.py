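"""Exception hierarchy shared across the pipeline."""


class MampscanError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MampscanError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(MampscanError):
    """Input violated an invariant of the data model."""


class ConfigError(MampscanError):
    """A configuration value is outside its allowed range."""
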