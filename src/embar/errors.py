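"""Exception types shared across the package."""


class EmbarError(Exception):
    """Base class for all package errors."""


class ValidationError(EmbarError, ValueError):
    """An input violated a documented precondition or invariant."""


class LogFormatError(ValidationError):
    """A browsing-history log file had malformed rows.

    Carries the offending 1-based line numbers so callers can report them.
    """

    def __init__(self, message: str, lines: list[int] | None = None):
        super().__init__(message)
        self.lines = lines or []
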