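"""Exception hierarchy shared across the package."""


class SeatradeError(Exception):
    """Base class for all package errors."""


class ConfigError(SeatradeError):
    """Invalid configuration or parameter value."""


class FoodWebError(SeatradeError):
    """Ill-posed food-web system (singular, cyclic without dominance, ...)."""


class TradeError(SeatradeError):
    """Gravity / flow-balancing failure."""


class ConvergenceError(TradeError):
    """Iterative proportional fitting did not reach the margin tolerance."""


class InfeasibleError(SeatradeError):
    """Supply/demand structure admits no feasible flow."""


class OptimizationError(SeatradeError):
    """Linear-programming solver returned a non-optimal status."""
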