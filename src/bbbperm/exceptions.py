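"""Exception hierarchy for bbbperm.

Every error raised by the library derives from :class:`BBBPermError`, so
callers can catch one type at a pipeline boundary while tests can assert
the specific failure mode.
"""


class BBBPermError(Exception):
    """Base class for all bbbperm errors."""


class InvalidMeasurementError(BBBPermError):
    """A chromatographic measurement violates its physical constraints
    (e.g. retention time not later than the dead time)."""


class InsufficientDataError(BBBPermError):
    """Too few observations for the requested fit (no residual degrees of
    freedom, or below the documented minimum)."""


class DegenerateDesignError(BBBPermError):
    """The design carries no usable variation (e.g. all mobile-phase
    compositions identical, or a zero-variance predictor)."""


class CollinearityError(BBBPermError):
    """The design matrix is rank deficient; perfectly collinear columns
    are named in the message."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class PairingError(BBBPermError):
    """Paired vectors of unequal length."""


class InconsistentInputError(BBBPermError):
    """Records that must share a key (e.g. a single column id) do not."""


class IncompleteRecordError(BBBPermError):
    """A compound record is missing a descriptor block or value required
    by the requested operation; the compound is named in the message."""


class FoldFailureError(BBBPermError):
    """A cross-validation fold could not be fitted."""

    def __init__(self, message, fold=None):
        super().__init__(message)
        self.fold = fold


class SchemaError(BBBPermError):
    """An input table does not match the expected schema."""
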