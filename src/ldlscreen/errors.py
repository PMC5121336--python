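"""Exception hierarchy shared across the package."""


class LDLScreenError(Exception):
    """Base class for all package errors."""


class DegeneratePlateError(LDLScreenError):
    """Raised when a plate's sample-well MAD is zero and no robust scale exists."""


class InsufficientControlsError(LDLScreenError):
    """Raised when a control group has too few finite values."""


class DivisionByZeroControlError(LDLScreenError):
    """Raised when negative- and positive-control means coincide."""


class ParseError(LDLScreenError):
    """Raised on malformed input tables; carries the offending row when known."""


class FitError(LDLScreenError):
    """Raised when a nonlinear fit fails to converge or is non-identifiable."""


class ImageError(LDLScreenError):
    """Raised on pathological image input (saturated or constant frames)."""
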