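"""Exception and warning types raised across the pipeline.

Every malformed input raises a typed error from this hierarchy; the
pipeline never propagates a silent NaN.
"""


class ShiftJudgeError(Exception):
    """Base class for all shiftjudge errors."""


class ValidationError(ShiftJudgeError):
    """A domain object violates one of its invariants."""


class DialectError(ShiftJudgeError):
    """An interchange file does not conform to the tabular dialect."""


class QCParseError(ShiftJudgeError):
    """Quantum-chemistry output text lacks or corrupts the shielding block."""


class InsufficientDataError(ShiftJudgeError):
    """Too few data points for the requested statistic or fit."""


class PositiveSlopeWarning(UserWarning):
    """The fitted shielding-vs-shift slope is positive.

    Shielding decreases as the chemical shift increases, so a physically
    sensible regression has a negative slope; a positive one usually means
    mismatched columns or a pathological dataset.
    """
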