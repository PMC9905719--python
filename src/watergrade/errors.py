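"""Exception hierarchy used across the package."""


class WatergradeError(Exception):
    """Base class for all package errors."""


class InputError(WatergradeError):
    """Unreadable, empty or otherwise unusable input data."""


class SchemaError(InputError):
    """A required column is missing or the column mapping is invalid."""


class ConfigError(InputError):
    """Invalid configuration value."""


class ValidationError(WatergradeError):
    """Arguments violate a documented precondition."""


class DegenerateColumnError(ValidationError):
    """A column (or reference series) carries no variation."""


class StratificationError(ValidationError):
    """A class is too small to stratify."""


class TrainingError(WatergradeError):
    """Model training cannot proceed (e.g. a single class in the data)."""


class OptimizationError(WatergradeError):
    """The optimizer encountered a non-finite objective value."""


class PipelineError(WatergradeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
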