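"""Exception hierarchy shared across the package."""


class WristcalError(Exception):
    """Base class for all package errors."""


class FormatError(WristcalError):
    """Malformed input artifact (missing column, bad JSON, ...)."""


class RowError(WristcalError):
    """One or more rows violated record invariants under strict policy."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = list(diagnostics or [])


class ConsistencyError(WristcalError):
    """Internally inconsistent values (e.g. FM total != upper + lower)."""


class RangeError(WristcalError):
    """Value outside its documented domain (score bounds, age bands, ...)."""


class DomainError(WristcalError):
    """Mathematical-domain violation (non-positive BMR, negative counts...)."""


class AlignmentError(WristcalError):
    """Instrument streams share no common minutes."""


class DegenerateInputError(WristcalError):
    """Single-class labels or otherwise uninformative input to ROC code."""


class DegenerateVarianceError(WristcalError):
    """A variance term required by a test statistic is zero."""


class InsufficientDataError(WristcalError):
    """A calibration slice lacks one of the intensity classes."""


class CalibrationInconsistencyError(WristcalError):
    """Derived boundaries violate SB < MVPA ordering."""


class ProvenanceError(WristcalError):
    """Ground truth and derived artifact come from different runs."""
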