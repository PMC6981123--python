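"""Exception hierarchy shared across gqion modules."""


class GQIonError(Exception):
    """Base class for all gqion errors."""


class ProtocolError(GQIonError):
    """Event times of an experimental protocol are inconsistent."""


class InsufficientDataError(GQIonError):
    """Too few data points for the requested analysis."""


class DegenerateTraceError(GQIonError):
    """A trace carries no net response (normalization impossible)."""


class FitError(GQIonError):
    """A nonlinear fit failed to converge.

    Carries the initial guess (and, when available, the optimizer's
    diagnostic message) so the caller can adjust starting values.
    """

    def __init__(self, message, initial_guess=None, diagnostics=None):
        super().__init__(message)
        self.initial_guess = initial_guess
        self.diagnostics = diagnostics


class NumericalError(GQIonError):
    """An internal numerical routine (root solve, equilibrium) failed."""


class InvalidDesignError(GQIonError):
    """The experimental design cannot support the analysis (e.g. a
    continuous-variation series whose maximum sits on the boundary)."""


class NoReversalError(GQIonError):
    """No zero-current crossing within (or near) the sampled voltage range."""


class ModelError(GQIonError):
    """A channel/permeation model violates its invariants."""


class StepSizeError(ModelError):
    """Integrator time step too large for the force field grid."""


class TrajectoryError(GQIonError):
    """An ion trajectory violates its invariants (gaps, wrapping)."""


class TableFormatError(GQIonError):
    """A tabular data file does not conform to the gqion CSV dialect."""
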