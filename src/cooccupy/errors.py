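"""Exception hierarchy.

Validation failures (bad inputs, broken invariants) map to CLI exit code 1;
anything else that escapes is a runtime failure, exit code 2.
"""


class CooccupyError(Exception):
    """Base class for package errors."""


class ValidationError(CooccupyError, ValueError):
    """An input violates a documented precondition or invariant."""


class ParseError(ValidationError):
    """A text record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ConfigurationError(CooccupyError, ValueError):
    """A simulation or pipeline configuration is infeasible."""
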