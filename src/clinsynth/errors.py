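"""Exception types shared across the pipeline stages."""


class ClinsynthError(ValueError):
    """Base class for all pipeline errors."""


class SchemaError(ClinsynthError):
    """A query, predicate or table references attributes that do not exist,
    or two tables that should share a schema do not."""


class ConfigError(ClinsynthError):
    """An invalid parameter configuration (unordered thresholds, bad bounds, ...)."""


class EmptyModelError(ClinsynthError):
    """Every stratum fell below the privacy threshold; no model can be fit."""


class SamplingError(ClinsynthError):
    """A sampling request cannot be satisfied (e.g. control pool exhausted)."""


class StratificationError(ClinsynthError):
    """A stratified split left one class absent from a partition."""
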