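"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration field is missing, inconsistent or out of range."""


class UndefinedOutcomeError(ValueError):
    """An outcome cannot be derived from the available follow-up data."""


class DegenerateDesignError(ValueError):
    """A regression design matrix is singular (e.g. all visit times equal)."""


class DegenerateFeatureError(ValueError):
    """A feature has zero spread on the training set, so it cannot be scaled."""


class DegenerateLabelsError(ValueError):
    """Training labels contain a single class."""


class UnsatisfiableConstraintsError(RuntimeError):
    """Rejection sampling exhausted its attempt budget."""


class UndefinedMetricError(ValueError):
    """A performance metric is undefined for the given inputs."""


class SchemaError(KeyError):
    """An expected column / feature is missing from a table."""


class ShapeError(ValueError):
    """Array shapes are incompatible with the requested operation."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


class ComparisonError(ValueError):
    """Model reports cannot be compared (e.g. different split plans)."""
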