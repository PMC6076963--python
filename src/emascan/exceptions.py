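"""Exception hierarchy for emascan.

Everything raised on purpose derives from :class:`EmaScanError` so callers can
catch package errors without swallowing programming bugs.
"""


class EmaScanError(Exception):
    """Base class for all emascan errors."""


class ParseError(EmaScanError):
    """A delimited input file could not be parsed; message names the line."""


class ValidationError(EmaScanError):
    """Input violated a documented precondition (negative count, duplicate prompt, ...)."""


class AlignmentError(EmaScanError):
    """A timestamp does not fall on the epoch grid."""


class OutOfRangeError(EmaScanError):
    """A prompt lies outside the recorded span of an activity series."""


class DegenerateFitError(EmaScanError):
    """Polynomial detrend requested with fewer points than coefficients."""


class UndefinedStatisticError(EmaScanError):
    """A moment is undefined on the window (too few points or zero variance)."""


class SingularDesignError(EmaScanError):
    """The fixed-effect design is rank deficient (e.g. constant predictor)."""


class InsufficientDataError(EmaScanError):
    """Too few subjects or observations to fit the requested model."""
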