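"""Exception hierarchy for the heatrisk pipeline."""


class HeatriskError(Exception):
    """Base class for all package errors."""


class InvalidInputError(HeatriskError, ValueError):
    """An input violates a documented precondition (range, shape, finiteness)."""


class OutOfBranchError(HeatriskError, ValueError):
    """The PMV-to-PT translation was called outside the heat branch (PMV < 0)."""


class NumericalFailureError(HeatriskError, RuntimeError):
    """An iterative solver failed to converge; carries diagnostics.

    Attributes
    ----------
    iterations : int
        Number of iterations performed before giving up.
    residual : float
        Last absolute update of the iterated quantity.
    """

    def __init__(self, message: str, iterations: int, residual: float):
        super().__init__(message)
        self.iterations = iterations
        self.residual = residual


class UnfitTableError(HeatriskError, ValueError):
    """A (threshold, lag) combination cannot support a regression
    (too few events or zero magnitude variance); skipped in grid search."""


class NoModelError(HeatriskError, RuntimeError):
    """No combination in the search grid produced enough events to fit."""
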