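"""Exception hierarchy shared across the pipeline stages."""


class BgcquantError(Exception):
    """Base class for all package errors."""


class InputError(BgcquantError):
    """An input file is missing, empty, or structurally invalid."""


class ParseError(InputError):
    """A record within an input file could not be parsed.

    Carries the 1-based line (or record) number when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class CatalogError(InputError):
    """The BGC catalog violates an integrity constraint."""


class StageError(BgcquantError):
    """A pipeline stage failed on otherwise readable input."""
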