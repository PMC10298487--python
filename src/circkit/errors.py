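"""Exception hierarchy shared across circkit modules."""


class CircKitError(Exception):
    """Base class for all circkit errors."""


class ValidationError(CircKitError, ValueError):
    """Input values violate a documented precondition."""


class ParseError(CircKitError, ValueError):
    """A structured text input could not be parsed.

    Carries the offending path and (1-based) line number when known so
    callers can point users at the exact record.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            if line is not None:
                loc += f":{line}"
            loc += "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)


class InsufficientDataError(CircKitError, ValueError):
    """Too few observations to compute the requested statistic."""


class DegenerateTableError(CircKitError, ValueError):
    """A contingency table has an empty margin."""


class UndefinedCorrelationError(CircKitError, ArithmeticError):
    """Correlation undefined because one variable has zero rank variance."""
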