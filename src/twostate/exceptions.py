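"""Exception types shared across the package."""


class TwoStateError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(TwoStateError, ValueError):
    """An argument lies outside the physical domain of the model.

    The message names the violated constraint (e.g. ``phiL + phiS <= 1``).
    """


class JumpNotFoundError(TwoStateError, RuntimeError):
    """No discontinuity of the equilibrium state distribution in the bracket."""


class ConvergenceError(TwoStateError, RuntimeError):
    """An iterative solver failed to reach its residual tolerance.

    Attributes
    ----------
    residual : float
        Best residual norm achieved.
    seed : tuple
        Starting point that was used.
    """

    def __init__(self, message, residual=None, seed=None):
        super().__init__(message)
        self.residual = residual
        self.seed = seed


class CuspAmbiguityError(TwoStateError, ValueError):
    """Evaluation exactly at a state-jump cusp without selecting a branch."""


class ResolutionError(TwoStateError, RuntimeError):
    """A grid was too coarse or too narrow to resolve the requested feature."""
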