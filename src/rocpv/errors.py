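"""Exception types shared across the package."""


class RocpvError(Exception):
    """Base class for all rocpv errors."""


class UndefinedStatisticError(RocpvError, ZeroDivisionError):
    """A statistic is undefined for the given input (e.g. zero denominator)."""


class InvalidRiskError(RocpvError, ValueError):
    """A '1 in N' risk is malformed or N <= 1."""


class InfeasibleCriteriaError(RocpvError, ValueError):
    """The requested performance criteria admit no solution in ROC space."""


class InvalidPointError(RocpvError, ValueError):
    """An operating point lies outside its valid domain."""


class SubjectAlignmentError(RocpvError, ValueError):
    """Two score vectors do not refer to the same subjects."""


class InputDataError(RocpvError, ValueError):
    """Tabular input is missing required columns or valid rows."""
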