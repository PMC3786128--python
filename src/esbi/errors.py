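"""Exception hierarchy shared across the package."""


class EsbiError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EsbiError, ValueError):
    """A value violates an instrument or record precondition."""


class SequencingError(EsbiError, RuntimeError):
    """A survey-flow operation was attempted out of page order."""


class StateError(EsbiError, RuntimeError):
    """A session is in the wrong lifecycle state for the operation."""


class SessionNotFoundError(EsbiError, KeyError):
    """No persisted session exists for the given linkage identifier."""


class ConfigError(EsbiError, ValueError):
    """Configuration is missing, malformed, or internally inconsistent."""


class ParseError(EsbiError, ValueError):
    """An input file failed to parse; carries a location when known."""

    def __init__(self, message: str, *, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        loc = ""
        if row is not None:
            loc += f" (row {row}"
            loc += f", column {column!r})" if column is not None else ")"
        elif column is not None:
            loc += f" (column {column!r})"
        super().__init__(message + loc)
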