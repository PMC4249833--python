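"""Exception hierarchy.

Validation failures (bad models, bad files, bad arguments) and numerical
failures (non-convergence, defective matrices) are kept distinct so the
command-line layer can map them to different exit codes.
"""


class PhenokinError(Exception):
    """Base class for all package errors."""


class ModelValidationError(PhenokinError, ValueError):
    """A model, observation set, or input file violates its contract."""


class DegenerateModelError(ModelValidationError):
    """A closed form does not apply (e.g. zero forward transition rate).

    Callers can opt in to the degenerate answer where one exists.
    """


class ConvergenceError(PhenokinError, RuntimeError):
    """An iterative or time-stepping computation failed to converge.

    Attributes
    ----------
    residual : float or None
        The residual (or distance) achieved when iteration stopped.
    """

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class DefectiveMatrixError(ConvergenceError):
    """The system matrix is numerically defective; use the integrator."""


class InfeasibleScanError(ConvergenceError):
    """No grid point passed the feasibility criteria.

    Attributes
    ----------
    violation_counts : dict
        Number of grid points rejected by each criterion.
    """

    def __init__(self, message, violation_counts=None):
        super().__init__(message)
        self.violation_counts = dict(violation_counts or {})
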