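"""Exception hierarchy shared across the package.

Everything derives from :class:`RdnaUnitError` so callers can catch one
type; most classes also derive from :class:`ValueError` so generic input
validation idioms keep working.
"""


class RdnaUnitError(Exception):
    """Base class for all package-specific errors."""


class ParseError(RdnaUnitError, ValueError):
    """A text input (FASTA/GFF3/WIG) could not be parsed.

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(RdnaUnitError, ValueError):
    """A domain object violates one of its invariants."""


class ParameterError(RdnaUnitError, ValueError):
    """An operation was called with an out-of-range parameter."""


class NoSignalError(RdnaUnitError, ValueError):
    """A coverage track carries no usable signal (e.g. all zero)."""


class NotFoundError(RdnaUnitError, LookupError):
    """A required sequence element was not found in the searched window."""


class SpecError(RdnaUnitError, ValueError):
    """A synthetic-unit specification is internally inconsistent."""
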