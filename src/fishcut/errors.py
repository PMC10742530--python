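"""Exception types raised across the pipeline."""


class FishcutError(Exception):
    """Base class for all fishcut errors."""


class InvalidArgumentError(FishcutError, ValueError):
    """An argument violates a documented precondition."""


class EmptyResultError(FishcutError, RuntimeError):
    """A stage produced no usable output (e.g. every frame segmented to belt)."""


class DegenerateColumnError(FishcutError, ValueError):
    """A feature column has zero variance and cannot be standardized."""


class TrainingDivergedError(FishcutError, RuntimeError):
    """An iterative fit produced a non-finite loss."""


class ParseError(FishcutError, ValueError):
    """A data file could not be parsed."""


class ConfigError(FishcutError, ValueError):
    """A configuration file contains unknown or invalid keys."""
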