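"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
NumericalError (and subclasses) -> 4.
"""


class PsafretError(Exception):
    """Base class for all package errors."""


class ConfigError(PsafretError):
    """Invalid or inconsistent configuration."""


class DataError(PsafretError):
    """Malformed or missing input data (files, stacks, ROIs)."""


class NumericalError(PsafretError):
    """Domain or conditioning failure in a numerical routine."""


class CalibrationError(NumericalError):
    """The g-factor reference data cannot yield a calibration."""


class DegenerateOpticsError(NumericalError):
    """Collection angle makes the polarization mixing model singular."""


class IllConditionedCorrectionError(NumericalError):
    """High-NA unmixing denominator too close to zero to invert safely."""


class FitError(NumericalError):
    """A regression could not be performed or did not converge."""
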