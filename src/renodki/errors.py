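"""Exception hierarchy for the renodki pipeline."""


class RenodkiError(Exception):
    """Base class for all package errors."""


class SchemeError(RenodkiError):
    """Invalid or unusable gradient scheme."""


class UnderdeterminedSchemeError(SchemeError):
    """Fewer than two nonzero shells: D and W cannot be separated."""


class InsufficientDirectionsError(SchemeError):
    """Too few directions to determine the 15 kurtosis components."""


class FormatError(RenodkiError):
    """Malformed or inconsistent file content."""


class FitError(RenodkiError):
    """Voxel fitting cannot proceed (bad input, unphysical parameters)."""


class CalibrationError(RenodkiError):
    """Tensor calibration target out of range or bisection failure."""


class PhantomSpecError(RenodkiError):
    """Inconsistent phantom specification (overlapping/too-small regions)."""


class StatsError(RenodkiError):
    """Statistical routine precondition violated."""


class ConfigError(RenodkiError):
    """Invalid run configuration."""
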