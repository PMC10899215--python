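"""Exception taxonomy shared across the package."""


class QAOPError(Exception):
    """Base class for all package-specific errors."""


class CycleError(QAOPError):
    """The proposed pathway graph contains a directed cycle."""


class UnknownNodeError(QAOPError, KeyError):
    """A node name does not exist in the graph."""


class RoleViolationError(QAOPError):
    """Node roles/phases violate the pathway taxonomy rules."""


class DesignError(QAOPError):
    """Study design is internally inconsistent (e.g. onset beyond E)."""


class DomainError(QAOPError, ValueError):
    """A quantity is outside its mathematical domain (e.g. f <= 0)."""


class DegenerateError(QAOPError):
    """Data are degenerate for the requested estimate (zero variance)."""


class SingularError(QAOPError):
    """A matrix that must be inverted is singular."""


class ConvergenceError(QAOPError):
    """An iterative fit failed to converge."""


class RankError(QAOPError):
    """A regression design matrix is rank deficient."""


class AlignmentError(QAOPError):
    """Rows of two exposure slices could not be matched."""


class EmptyWindowError(QAOPError):
    """No Monte-Carlo sample fell inside the requested dose window."""


class EmptyConditioningError(QAOPError):
    """No simulated trajectory satisfied the conditioning event."""


class GridError(QAOPError, ValueError):
    """An integration grid is malformed (not ascending / too short)."""
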