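"""Exception hierarchy.

All fairpost errors derive from :class:`FairpostError` so callers can catch
the whole family; the concrete classes mirror the failure modes of the
pipeline (bad arguments, schema mismatches, degenerate groups, undefined
rates, infeasible resampling plans, policy-fitting failures).
"""


class FairpostError(Exception):
    """Base class for all fairpost errors."""


class InvalidArgumentError(FairpostError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(FairpostError, KeyError):
    """A dataset or score container is missing a required column/attribute."""


class EncodingError(SchemaError):
    """A column could not be mapped to the required binary 0/1 coding."""


class DegenerateGroupError(FairpostError):
    """A protected group is absent from the data."""

    def __init__(self, group: int, message: str | None = None):
        self.group = group
        super().__init__(message or f"group {group} is absent from the data")


class UndefinedRateError(FairpostError, ZeroDivisionError):
    """A per-group rate (TPR/FPR) has an empty denominator."""


class UndefinedMetricError(FairpostError, ZeroDivisionError):
    """A pooled metric (balanced accuracy, F1) is undefined for this input."""


class UndefinedCorrelationError(FairpostError):
    """A correlation is undefined (e.g. a constant attribute column)."""


class InfeasiblePlanError(FairpostError):
    """A resampling plan cannot be satisfied by the available rows."""


class FitError(FairpostError):
    """A debiasing policy could not be fitted (degenerate group or class)."""


class ConvergenceError(FitError):
    """A policy optimizer failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class AdapterContractError(FairpostError):
    """A model adapter emitted scores outside [0, 1]."""
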