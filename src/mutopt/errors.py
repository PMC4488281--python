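"""Exception hierarchy shared across the package."""


class MutoptError(Exception):
    """Base class for all package errors."""


class DegenerateChainError(MutoptError):
    """Markov chain is reducible or periodic; no unique stationary distribution."""


class ReversibilityError(MutoptError):
    """Matrix violates detailed balance for the given stationary distribution."""

    def __init__(self, residual: float):
        self.residual = residual
        super().__init__(
            f"matrix is not reversible: max detailed-balance residual {residual:.3e}"
        )


class InfeasibleConstraintError(MutoptError):
    """Eigenvalue constraint cannot be satisfied in the admissible range."""


class SamplingError(MutoptError):
    """Rejection sampler exhausted its retry budget."""

    def __init__(self, attempts: int):
        self.attempts = attempts
        super().__init__(
            f"no valid transition matrix found after {attempts} attempts"
        )


class ValidationError(MutoptError):
    """Input file or value failed validation."""


class ParseError(MutoptError):
    """Malformed input file."""
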