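"""Exception hierarchy for pgropt."""


class PgroptError(Exception):
    """Base class for all pgropt errors."""


class ConfigError(PgroptError):
    """Invalid configuration: missing columns, bad option values."""


class TableParseError(PgroptError):
    """A delimited treatment table could not be parsed."""


class DegenerateScaleError(PgroptError):
    """A column has zero range and cannot be mapped to a target interval."""


class InvalidSplitError(PgroptError):
    """A train/test split would leave a partition empty."""


class TrainingDivergenceError(PgroptError):
    """The network objective became non-finite during training."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class UndefinedMetricError(PgroptError):
    """A requested metric is undefined for the given data (e.g. zero variance)."""


class EvaluationError(PgroptError):
    """A surrogate evaluator returned a non-finite objective."""
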