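"""Exception types shared across the package."""


class OsmoEngineError(Exception):
    """Base class for all package errors."""


class ParameterError(OsmoEngineError, ValueError):
    """A model parameter violates an invariant; the message names the field."""


class InvalidInputError(OsmoEngineError, ValueError):
    """An operation received an argument outside its domain."""


class InfeasibleStateError(OsmoEngineError):
    """No physically admissible state exists for the given parameters."""


class NonConvergenceError(OsmoEngineError):
    """The Newton/continuation solver failed to reach the residual tolerance.

    Carries the best iterate and a per-block residual report so the failure
    is inspectable rather than silent.
    """

    def __init__(self, message, best_state=None, block_norms=None):
        super().__init__(message)
        self.best_state = best_state
        self.block_norms = dict(block_norms or {})


class NumericalFailureError(NonConvergenceError):
    """A residual evaluation produced NaN/inf; names the offending block."""


class GenerationError(OsmoEngineError):
    """A synthetic-data generator could not produce its output."""


class UndefinedRatioError(OsmoEngineError):
    """A polarization ratio is undefined (a pole window has no signal)."""
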