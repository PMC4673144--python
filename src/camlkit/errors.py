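"""Exception types shared across the pipeline."""


class CamlError(Exception):
    """Base class for all camlkit errors."""


class InputError(CamlError, ValueError):
    """Invalid input data or arguments."""


class ParseError(InputError):
    """A malformed line in a text input file.

    Carries the offending line number (1-based) when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ConfigError(CamlError, ValueError):
    """Inconsistent or unsatisfiable configuration."""
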