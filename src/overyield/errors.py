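"""Exception and warning types shared across the package."""


class OveryieldError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(OveryieldError, ValueError):
    """A value violates an operation's preconditions (e.g. non-positive diameter)."""


class ConsistencyError(OveryieldError):
    """Cross-table inconsistency, e.g. a tree referencing an unknown plot."""


class UndefinedMetricError(OveryieldError):
    """A metric is mathematically undefined for the given input (zero mean, empty community)."""


class InvalidModelError(OveryieldError):
    """A model specification is structurally invalid (e.g. cyclic SEM graph)."""


class ConvergenceError(OveryieldError):
    """An optimizer failed to converge; carries the optimizer trace for diagnosis."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class SingularFitWarning(UserWarning):
    """A random-effect variance collapsed to (numerically) zero; the fit is retained."""


class DegenerateScalingWarning(UserWarning):
    """A scaling group had zero spread; its values were mapped to zero."""


class RankWarning(UserWarning):
    """Fewer observations than variables in a decomposition; results may be rank-deficient."""
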