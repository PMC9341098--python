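"""Exception hierarchy.

All package-specific failures derive from :class:`OctamagError` so callers
can distinguish domain errors from programming errors.  Configuration
problems (bad device registry, unresolvable options) and data-validation
problems (impossible measurements, unpairable samples) are separate
branches because the command-line layer maps them to different exit codes.
"""


class OctamagError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(OctamagError):
    """Invalid configuration: device registry, model file, option conflict."""


class DataValidationError(OctamagError):
    """Base class for errors caused by invalid input data."""


class InvalidMeasurementError(DataValidationError):
    """A biometric measurement is physically impossible (e.g. K <= 0)."""


class InvalidAxialLengthError(DataValidationError):
    """Axial length at or below the 1.82 mm corneal-apex offset of the
    Littmann-Bennett formula, where the ocular magnification q is undefined."""


class FittingError(DataValidationError):
    """Regression cannot be fitted: too few rows or rank-deficient design."""


class InsufficientDataError(DataValidationError):
    """Too few paired observations for the requested statistic."""


class UndefinedStatisticError(DataValidationError):
    """The statistic is undefined on this input (e.g. zero variance)."""


class PairingError(DataValidationError):
    """The two measurement vectors cannot be paired (length mismatch)."""


class InvalidDenominatorError(DataValidationError):
    """A reference value used as denominator is zero or negative."""
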