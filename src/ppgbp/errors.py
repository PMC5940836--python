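"""Exception hierarchy shared across the pipeline.

Two bases map onto the CLI exit-code convention: bad or malformed input
(exit 2) versus a computation that degenerates on structurally valid input
(exit 3).
"""


class PpgbpError(Exception):
    """Base class for all errors raised by this package."""


class InputError(PpgbpError):
    """The input data or configuration is invalid (CLI exit code 2)."""


class ComputationError(PpgbpError):
    """A computation degenerated on otherwise valid input (CLI exit code 3)."""


class SignalTooShort(InputError):
    """The PPG record is shorter than the minimum analyzable duration."""


class NoBeatsFound(ComputationError):
    """Beat detection found no pulsatile activity in the signal."""


class InvalidFilterConfig(InputError):
    """Band edges are infeasible for the record's sampling rate."""


class NonPositiveDC(InputError):
    """A beat's DC level is not positive (un-offset or inverted input)."""


class InsufficientData(InputError):
    """Too few calibration rows to fit the regression model."""


class DegenerateDesign(ComputationError):
    """The regression design matrix is rank deficient."""


class DegenerateInput(ComputationError):
    """A statistic is undefined for this input (e.g. zero variance)."""


class UnpairedData(InputError):
    """Paired-vector statistics received vectors of unequal length."""


class InvalidReading(InputError):
    """A blood-pressure reading violates SBP > DBP > 0."""


class InfeasibleProfile(InputError):
    """A simulated heart-rate profile implies beats faster than the refractory period."""


class IncoherentModel(InputError):
    """Generating coefficients imply SBP <= DBP; the caller must adjust them."""
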