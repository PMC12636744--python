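"""Shared exception types."""


class VaxbiomeError(Exception):
    """Base class for package errors."""


class ValidationError(VaxbiomeError, ValueError):
    """A value or field violates its contract."""


class ParseError(VaxbiomeError, ValueError):
    """An on-disk table could not be parsed.

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class JoinError(VaxbiomeError, KeyError):
    """Sample sets of two tables do not match."""


class ModelError(VaxbiomeError, ValueError):
    """A statistical model could not be constructed or fitted."""
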