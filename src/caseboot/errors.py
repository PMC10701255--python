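"""Exception hierarchy for caseboot.

The CLI maps these onto exit codes: schema/data problems exit 2, model
non-convergence exits 3, bootstrap reliability failures exit 4.
"""


class CasebootError(Exception):
    """Base class for all caseboot errors."""


class SchemaError(CasebootError):
    """A required column is missing or a cell cannot be parsed."""


class DataIntegrityError(CasebootError):
    """IDs violate uniqueness/duplication rules."""


class MissingDataError(CasebootError):
    """Missing values in covariate columns (no imputation is performed)."""


class DegenerateDataError(CasebootError):
    """Input is structurally unusable (e.g. single-valued D, empty stratum)."""


class RankDeficiencyError(CasebootError):
    """Design matrix does not have full column rank."""


class SingularityError(CasebootError):
    """Information matrix is numerically singular."""


class NonConvergenceError(CasebootError):
    """IRLS failed to converge (includes separation).

    Carries the iteration state so callers can inspect how far the
    optimizer got before giving up.
    """

    def __init__(self, message, beta=None, n_iter=None):
        super().__init__(message)
        self.beta = beta
        self.n_iter = n_iter


class ReliabilityError(CasebootError):
    """Too many bootstrap replicates failed to converge."""


class CalibrationError(CasebootError):
    """Intercept calibration is infeasible (event probability above 1)."""


class GenerationError(CasebootError):
    """Cohort generation produced an invalid event probability."""
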