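"""Exception hierarchy shared by all growthdom stages."""


class GrowthdomError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GrowthdomError):
    """Input data or configuration violates a documented precondition."""


class UndefinedResultError(GrowthdomError):
    """The requested statistic is mathematically undefined for this input
    (e.g. total growth <= 0 after the negative-growth policy)."""


class DegenerateFitError(GrowthdomError):
    """A regression cannot be fitted (e.g. zero variance in the predictor)."""


class ConfigurationError(GrowthdomError):
    """A configuration table is missing a required entry."""


class SubsampleSkip(GrowthdomError):
    """Raised when a requested subsample size exceeds the trees available.

    Callers iterating over plots catch this to skip the plot explicitly;
    it is an exception (not a silent omission) so single-plot callers fail
    loudly.
    """


class UnmappedIntervalError(GrowthdomError):
    """A census pair does not fall inside any configured growth period."""
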