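"""Exception hierarchy for the bowkin pipeline."""


class BowkinError(Exception):
    """Base class for all pipeline errors."""


class FormatError(BowkinError):
    """A file does not conform to the expected on-disk format."""


class ParseError(FormatError):
    """A row-level parse failure; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ParameterError(BowkinError, ValueError):
    """An argument is outside its documented valid range."""


class AlignmentError(BowkinError):
    """Two streams cannot be placed on a common clock."""


class ConfigurationError(BowkinError):
    """A required role or key is missing from a configuration mapping."""


class DegenerateGeometryError(BowkinError):
    """Marker geometry is degenerate (e.g. collinear) at some frame."""

    def __init__(self, message: str, frame: int | None = None):
        self.frame = frame
        if frame is not None:
            message = f"frame {frame}: {message}"
        super().__init__(message)
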