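"""Exception hierarchy for telomap."""


class TelomapError(Exception):
    """Base class for all telomap errors."""


class InvalidParameterError(TelomapError, ValueError):
    """A parameter violates its documented precondition."""


class UnknownProfileError(TelomapError, KeyError):
    """Requested cell-line profile is not packaged."""


class UnknownArmError(TelomapError, KeyError):
    """Requested chromosome arm is not in the reference set."""


class CalibrationError(TelomapError):
    """A length-distribution tail cannot be calibrated to the requested mass."""


class ParseError(TelomapError):
    """A molecule/reference file is malformed.

    Carries the 1-based line number at which the problem was detected.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConsistencyError(TelomapError):
    """In-memory data violates a structural invariant (refused at I/O)."""


class InsufficientDataError(TelomapError):
    """Not enough observations for the requested statistic."""
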