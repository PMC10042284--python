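"""Exception hierarchy shared across the pipeline stages."""


class RicencError(Exception):
    """Base class for all package-specific errors."""


class InvalidSampleError(RicencError, ValueError):
    """A plant sample violates its invariants (e.g. zero sampled tillers)."""


class InvalidWeatherError(RicencError, ValueError):
    """A weather record violates its invariants (e.g. tmax < tmin)."""


class InvalidWindowError(RicencError, ValueError):
    """An empty or malformed thermal-time accumulation window."""


class UnderdeterminedFitError(RicencError, ValueError):
    """Too few (or degenerate) points to identify the curve parameters."""


class FitError(RicencError, RuntimeError):
    """Nonlinear least squares failed to converge."""


class InsufficientDataError(RicencError, ValueError):
    """Fewer values than a statistic requires."""


class DomainError(RicencError, ValueError):
    """An argument outside the mathematical domain of an operation."""


class InsufficientReplicationError(RicencError, ValueError):
    """A treatment has fewer replicates than the ANOVA needs."""


class NonResponsiveDateError(RicencError, ValueError):
    """Biomass does not increase with plant N at a sampling date."""


class ConfigError(RicencError, ValueError):
    """A configuration object violates its invariants."""


class SamplerFailureError(RicencError, RuntimeError):
    """The MCMC sampler stalled (zero acceptance after adaptation)."""


class InsufficientDrawsError(RicencError, ValueError):
    """Too few posterior draws to summarize."""


class MappingError(RicencError, KeyError):
    """Samples reference groups with no specific curve available."""
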