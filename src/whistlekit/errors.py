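"""Exception hierarchy shared across the package."""


class WhistlekitError(Exception):
    """Base class for all whistlekit errors."""


class InvalidParameterError(WhistlekitError, ValueError):
    """A configuration value or function parameter is out of range."""


class InvalidInputError(WhistlekitError, ValueError):
    """Input data violates a precondition (empty, mismatched, malformed)."""


class InfeasibleAlignmentError(WhistlekitError):
    """No warp path satisfies the slope constraint for the two contours."""


class DegenerateInputError(WhistlekitError, ValueError):
    """Input is structurally valid but degenerate for the requested statistic."""


class UndefinedStatisticError(WhistlekitError, ValueError):
    """The requested statistic is undefined for this input (e.g. p_e == 1)."""


class ParseError(WhistlekitError, ValueError):
    """A file could not be parsed into the expected tabular layout."""
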