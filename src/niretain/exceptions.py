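"""Exception hierarchy for niretain.

All package-specific errors derive from :class:`NiRetainError` so callers can
catch everything with one clause; each also derives from the closest builtin
(``ValueError``/``ZeroDivisionError``) so generic handling keeps working.
"""


class NiRetainError(Exception):
    """Base class for all niretain errors."""


class InvalidParameterError(NiRetainError, ValueError):
    """A numeric parameter is outside its domain (non-finite, wrong sign, ...)."""


class DegenerateDenominatorError(NiRetainError, ZeroDivisionError):
    """The historical-effect estimate is exactly zero, so ratio-based
    statistics (Wang, ratio test, observed retention fraction) are undefined."""


class InsufficientDataError(NiRetainError, ValueError):
    """Fewer than two observations in an arm: variance is undefined."""


class ParseError(NiRetainError, ValueError):
    """An input table failed validation; the message names row and column."""


class WrongEngineError(NiRetainError, TypeError):
    """A simulation method was routed to the wrong simulation engine."""
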