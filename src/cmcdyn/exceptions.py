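"""Exception hierarchy for cmcdyn."""


class CMCError(Exception):
    """Base class for all cmcdyn errors."""


class NonFiniteStateError(CMCError):
    """A state vector contains NaN or infinite entries."""


class StabilityError(CMCError):
    """A requested integration step violates a stability bound."""


class ConvergenceRadiusError(CMCError):
    """A truncated drift series was evaluated outside its convergence radius."""


class TailMassError(CMCError):
    """The stationary density has non-negligible mass at the grid boundary."""


class GridMismatchError(CMCError):
    """Two objects that must share an amplitude grid do not."""


class DegenerateExtremumError(CMCError):
    """An extremum with vanishing curvature was used where curvature is required."""


class NoBarrierError(CMCError):
    """A state has no adjacent interior barrier to escape over."""


class BarrierLossError(CMCError):
    """A parameter scaling destroyed the barrier structure of the potential."""


class PipelineError(CMCError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
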