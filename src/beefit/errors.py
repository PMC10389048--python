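"""Exception types shared across the package."""


class BeefitError(Exception):
    """Base class for all beefit errors."""


class InvalidInputError(BeefitError, ValueError):
    """An input violates a documented precondition (non-finite, wrong shape...)."""


class SingularRateError(BeefitError, ZeroDivisionError):
    """A rate law was evaluated at a singular point (e.g. Glci=0 with Km>0)."""


class SimulationError(BeefitError, RuntimeError):
    """ODE integration failed; carries the time at which it failed."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class GridMismatchError(BeefitError, ValueError):
    """Two time series do not share the identical time grid."""


class DegenerateColonyError(BeefitError, RuntimeError):
    """The bee colony reached a state the algorithm cannot proceed from."""
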