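"""Exception hierarchy."""


class IdealizeError(Exception):
    """Base class for all package errors."""


class FormatError(IdealizeError):
    """Unparsable or malformed input file."""


class InputTooShortError(IdealizeError):
    """No pair of consecutive complete residues to work with."""


class DegenerateGeometryError(IdealizeError):
    """Coincident or collinear points where a frame is required."""


class ChainBreakError(IdealizeError):
    """A gap in the backbone where a gapless trace is required."""
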