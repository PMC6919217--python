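"""Exception types raised across the package."""


class CondsurvError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CondsurvError):
    """An input table is missing a required (mapped) column."""


class CohortValidationError(CondsurvError):
    """A record violates an admission-table invariant (e.g. negative LOS)."""


class EmptyCohortError(CondsurvError):
    """An operation received a cohort with no usable records."""


class UndefinedIntervalError(CondsurvError):
    """A binomial interval was requested with zero trials."""


class EmptyCurveError(CondsurvError):
    """The cohort is too small to report any day at the requested threshold."""


class ParameterError(CondsurvError):
    """Invalid synthetic-cohort or analysis parameters."""


class DomainError(CondsurvError):
    """Degenerate conditioning: essentially no mass at or beyond the requested day."""


class UnderdeterminedFitError(CondsurvError):
    """A local regression neighborhood has too few points for the polynomial degree."""


class NoCurveError(CondsurvError):
    """Plotting was requested but every curve is empty."""
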