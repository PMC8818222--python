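"""Exception hierarchy shared across the pipeline."""


class CsfCircError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(CsfCircError, ValueError):
    """A configuration value violates its documented constraints."""


class ParseError(CsfCircError, ValueError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class DegenerateDataError(CsfCircError, ValueError):
    """Input is structurally valid but statistically degenerate
    (e.g. all paired differences zero, constant values, single group)."""
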