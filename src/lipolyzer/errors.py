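"""Exception hierarchy. Each maps to a distinct CLI exit code."""


class LipolyzerError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(LipolyzerError):
    """Input values violate a documented invariant."""

    exit_code = 2


class ParseError(LipolyzerError):
    """A delimited-text input file could not be parsed."""

    exit_code = 3


class CalibrationError(LipolyzerError):
    """Calibration data unusable or missing for a requested target."""

    exit_code = 4
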