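"""Domain-specific exceptions.

Every error raised on a violated precondition derives from
:class:`InvascapeError` so callers can catch package failures narrowly.
"""


class InvascapeError(Exception):
    """Base class for all package errors."""


class InvalidDomainError(InvascapeError, ValueError):
    """An argument lies outside its mathematically valid domain."""


class SchemaError(InvascapeError, ValueError):
    """An input table is missing a required column or has a bad dtype."""


class SystemValidationError(InvascapeError, ValueError):
    """A unit system violates its geometric invariants (e.g. overlaps)."""


class DegenerateWeightsError(InvascapeError, ValueError):
    """A spatial-weights structure cannot be built (e.g. a single unit)."""


class UndefinedStatisticError(InvascapeError, ValueError):
    """A statistic is undefined for the given input (e.g. constant x)."""


class InsufficientUnitsError(InvascapeError, ValueError):
    """Too few areal units for the requested inference."""


class InfeasibleRhoError(InvascapeError, ValueError):
    """The spatial-lag coefficient lies outside the feasible interval."""


class SingularDesignError(InvascapeError, ValueError):
    """The regression design matrix is rank deficient."""


class ImputationImpossibleError(InvascapeError, ValueError):
    """No observed donor units are available for imputation."""


class SelectionImpossibleError(InvascapeError, ValueError):
    """No candidate unit system admits a valid Moran's I statistic."""


class ArtifactMissingError(InvascapeError, FileNotFoundError):
    """A pipeline stage output required by a later stage is absent."""
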