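"""Exception hierarchy for the screening pipeline.

Every stage raises a subclass of :class:`GraphoScreenError` so callers can
distinguish bad inputs from degenerate-but-well-formed data (e.g. a series
too short to window, or a label vector with a single class).
"""


class GraphoScreenError(Exception):
    """Base class for all package errors."""


class InvalidInputError(GraphoScreenError):
    """Malformed input: non-monotone timestamps, mismatched lengths, bad enum values."""


class DegenerateSeriesError(GraphoScreenError):
    """A series that cannot be processed: zero time span or fewer than 2 samples."""


class ShortSeriesError(GraphoScreenError):
    """A channel shorter than one window; the caller may skip the sample."""


class TrainingDivergenceError(GraphoScreenError):
    """Non-finite loss encountered while training a model."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class DegenerateWeightsError(GraphoScreenError):
    """All-zero decoder weights under the normalised aggregation mode."""


class InsufficientLandmarksError(GraphoScreenError):
    """Fewer extrema available than the requested number of landmarks."""


class DegenerateShapeError(GraphoScreenError):
    """A landmark set with zero variance after centering."""


class DegenerateLabelsError(GraphoScreenError):
    """A label vector containing a single class where two are required."""


class UnfitConfigurationError(GraphoScreenError):
    """Every unit classifier was dropped; the configuration cannot be fitted."""


class UnpredictableChildError(GraphoScreenError):
    """A child with no usable unit inputs at prediction time."""


class InfeasibleStratificationError(GraphoScreenError):
    """A class too small to stratify into the requested folds."""


class MissingGameError(GraphoScreenError):
    """A game required by the meta-model is absent from the supplied records."""


class ConfigurationWarning(UserWarning):
    """Non-fatal configuration issue (e.g. expected positives < 1)."""
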