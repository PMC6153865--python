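"""Exception types shared across the package."""


class LanderError(Exception):
    """Base class for package errors."""


class ParseError(LanderError, ValueError):
    """A file cell could not be parsed; the message names row and column."""


class ValidationError(LanderError, ValueError):
    """A record or table violates a domain invariant."""


class TransformError(LanderError, ValueError):
    """An abundance transform was requested on an incompatible matrix."""


class DegenerateModelError(LanderError, ArithmeticError):
    """A model fit is degenerate (e.g. zero residual variance)."""
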