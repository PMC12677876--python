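"""Exception hierarchy shared across the pipeline stages."""


class ActimoodError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ActimoodError):
    """Invalid generator / pipeline configuration."""


class MalformedInputError(ActimoodError):
    """Input table or series violates the expected schema (e.g. not 1440 epochs)."""


class InsufficientDataError(ActimoodError):
    """Not enough valid data to compute a feature (e.g. k nonoverlapping windows)."""


class MissingFeatureError(ActimoodError):
    """A required upstream feature is missing; never silently coerced to zero."""


class DegenerateInputError(ActimoodError):
    """Statistical routine called on degenerate input (single group, <2 obs, ...)."""


class BinningDegenerateError(DegenerateInputError):
    """Fewer than 4 distinct values: equal-frequency quartiles are undefined."""


class EffectSizeDomainError(ActimoodError):
    """Effect size outside its mathematical domain."""


class IntegrityError(ActimoodError):
    """Data integrity / leakage-guard violation (duplicate keys, mood column in X)."""


class SplitError(ActimoodError):
    """Grouped cross-validation split infeasible (fewer patients than folds)."""


class ValidationError(ActimoodError):
    """Pipeline configuration file failed validation; message lists missing keys."""


class StageError(ActimoodError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
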