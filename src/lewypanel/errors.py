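"""Exception hierarchy shared across the package."""


class DataError(ValueError):
    """Input data violates a precondition (dimensions, classes, ranges)."""


class FormatError(DataError):
    """A file does not conform to the expected tabular layout."""


class ParseError(DataError):
    """A cell could not be parsed; carries a row index when known."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row
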