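"""Named exceptions raised across the pipeline.

Every rejection contract in the public API raises one of these instead of a
bare ValueError so callers can distinguish validation failures from bugs.
"""


class NeurocogError(Exception):
    """Base class for all package-specific errors."""


class InvalidPhaseError(NeurocogError):
    """Recording phase label is not one of {'REC', 'ENC'}."""


class NonPositiveDefiniteError(NeurocogError):
    """A covariance matrix is not symmetric positive semi-definite."""


class MissingMarkerError(NeurocogError):
    """A planted/requested marker column is absent from the table."""


class RecordingTooShortError(NeurocogError):
    """Recording shorter than the filter transient (or otherwise unusable)."""


class AllEpochsRejectedError(NeurocogError):
    """Every epoch was flagged as artifact; the recording is unusable."""


class NoUnmaskedEpochsError(NeurocogError):
    """An operation requiring clean epochs found none."""


class InsufficientEpochsError(NeurocogError):
    """Too few epochs for a stable estimate (e.g. coherence needs >= 8)."""


class DegenerateSpectrumError(NeurocogError):
    """Spectral mass is zero where the estimator needs it (e.g. 8-13 Hz)."""


class TableValidationError(NeurocogError):
    """A tabular input failed validation; message names the row/column."""


class NormalizationError(NeurocogError):
    """ICV normalization precondition violated (icv <= 0, double-normalize)."""


class RankDeficientError(NeurocogError):
    """Design matrix is rank deficient / collinear beyond tolerance."""


class EnumerationBudgetError(NeurocogError):
    """All-subset enumeration would exceed the fit budget."""


class SingleClassError(NeurocogError):
    """A training fold (or the cohort) contains only one class."""


class EmptyGroupError(NeurocogError):
    """A group comparison was requested with an empty group."""


class ConfigError(NeurocogError):
    """Run configuration failed schema validation."""
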