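"""Exception hierarchy shared across the package.

CLI exit-code mapping: ValidationError -> 2, ExternalToolError -> 3,
InputOutputError (and OSError) -> 4.
"""


class GenomeRingError(Exception):
    """Base class for all package errors."""


class ValidationError(GenomeRingError):
    """Invalid arguments, profile contents, or domain-object invariant breach."""


class ParseError(GenomeRingError):
    """A file did not conform to its declared format."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += str(path)
        if line is not None:
            prefix += f":{line}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


class ExternalToolError(GenomeRingError):
    """An external executable (BLAST+) was missing or exited non-zero."""


class InputOutputError(GenomeRingError):
    """Unreadable or unwritable path."""
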