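"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A model or monitoring parameter is outside its valid range."""


class InvalidInputError(ValueError):
    """An input object violates a structural precondition (shape, symmetry...)."""


class InsufficientHistoryError(ValueError):
    """A sequence is too short to establish the scan's moving-window baseline."""


class ParseError(ValueError):
    """A data file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnknownFixtureError(KeyError):
    """Requested fixture name is not in the catalogue."""
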