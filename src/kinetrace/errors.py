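"""Exception hierarchy shared across the package.

Every error raised by kinetrace derives from :class:`KinetraceError` so that
callers (and the CLI) can catch the package's failures without swallowing
programming errors.
"""


class KinetraceError(Exception):
    """Base class for all kinetrace errors."""


class ValidationError(KinetraceError, ValueError):
    """Structurally invalid domain object (bad bounds, mixed arguments, ...)."""


class TraceLookupError(KinetraceError, KeyError):
    """A trace name does not exist in the experiment."""


class ParseError(KinetraceError, ValueError):
    """Malformed raw-trace file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InsufficientDataError(KinetraceError, ValueError):
    """Not enough samples or points for the requested analysis."""


class ReadOnlyError(KinetraceError, PermissionError):
    """A mutating operation was attempted while the store is read-only."""


class SchemaVersionError(KinetraceError, RuntimeError):
    """The store schema is newer than this version of the code supports."""


class RegistryError(KinetraceError, RuntimeError):
    """Module registration conflict or dispatch failure."""
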