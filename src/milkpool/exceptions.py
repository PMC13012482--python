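"""Exception hierarchy for milkpool.

All errors raised on bad input derive from :class:`MilkpoolError` so callers
can catch one base class; the subclasses distinguish the failure classes the
pipeline contracts name (schema vs referential vs value validation, etc.).
"""


class MilkpoolError(Exception):
    """Base class for all milkpool errors."""


class SchemaError(MilkpoolError):
    """A tabular input is missing a required column or has a malformed one."""


class ReferentialError(MilkpoolError):
    """A record refers to an entity (donor, bottle) that does not exist."""


class ValidationError(MilkpoolError, ValueError):
    """A value violates a domain invariant (non-positive volume, bad dates...)."""


class UndefinedCorrelationError(MilkpoolError):
    """Pearson correlation requested against a constant vector."""


class CollinearityError(MilkpoolError):
    """Regression design matrix is rank deficient."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class UnsupportedModelError(MilkpoolError):
    """Operation requires a model type that the given model is not."""


class EnumerationBoundError(MilkpoolError):
    """Brute-force oracle asked to enumerate an instance above its size bound."""


class InfeasibleError(MilkpoolError):
    """Optimisation model has no feasible assignment.

    ``reason`` identifies the first violated requirement class found by
    elastic diagnosis: ``"volume"`` or ``"donor-count"``.
    """

    def __init__(self, message: str, reason: str = "unknown"):
        super().__init__(message)
        self.reason = reason
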