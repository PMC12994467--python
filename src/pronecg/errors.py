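"""Exception and warning types shared across the toolkit."""


class ProneCGError(Exception):
    """Base class for all toolkit errors."""


class FormatError(ProneCGError):
    """A file could not be parsed under the requested dialect."""


class MissingLead(ProneCGError):
    """A required ECG lead is absent from a record or file."""


class LengthMismatch(ProneCGError):
    """Paired series have incompatible lengths."""


class EdgeBeat(ProneCGError):
    """An R peak has insufficient signal context for delineation."""


class InsufficientData(ProneCGError):
    """Too few sample points to fit the requested regression."""


class ModelNotFitted(ProneCGError):
    """Conversion requested from a model that has not been fitted."""


class SchemaMismatch(ProneCGError):
    """Model predictor schema does not match the supplied record."""


class ConfigError(ProneCGError):
    """Invalid synthetic-cohort configuration."""


class MissingCovariate(ProneCGError):
    """A required subject covariate is absent."""


class UndelineatedBeat(ProneCGError):
    """A beat lacks the fiducials needed to build feature tables."""


class EmptySlot(ProneCGError):
    """A (lead, segment) training table is empty."""


class TooManyFolds(ProneCGError):
    """More cross-validation folds requested than subjects available."""


class WindowMismatch(ProneCGError):
    """Hybrid combination requires both beats to share segment windows."""


class DegenerateTarget(ProneCGError):
    """Constant target series: the coefficient of determination is undefined."""


class MissingClass(ProneCGError):
    """The requested positive class is absent from the truth labels."""


class EmptyQRS(ProneCGError):
    """No QRS deflection exceeds the flat threshold."""


class LeakageError(ProneCGError):
    """A subject appears on both sides of a train/test partition."""


class RankDeficientWarning(UserWarning):
    """Predictor matrix is rank deficient; minimum-norm solution returned."""
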