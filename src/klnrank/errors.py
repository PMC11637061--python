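"""Exception hierarchy shared across the package."""


class KlnrankError(Exception):
    """Base class for all package-specific errors."""


class ParseError(KlnrankError, ValueError):
    """Malformed input file (edge list or GML)."""


class GraphDomainError(KlnrankError, ValueError):
    """A precondition on the graph or its nodes was violated
    (unknown node, too few nodes, empty seed set, ...)."""


class ConvergenceError(KlnrankError, RuntimeError):
    """An iterative solver did not converge within its iteration cap."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DegenerateDistributionError(KlnrankError, ValueError):
    """A probability row whose raw weights are all zero and cannot be
    normalized (only possible with a zero degree floor)."""
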