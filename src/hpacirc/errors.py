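"""Exception types shared across the package."""


class HpacircError(Exception):
    """Base class for package-specific errors."""


class NonConvergence(HpacircError):
    """Limit-cycle (or phase-lock) iteration did not meet its criterion.

    Carries the last residual so callers can report how far off it was.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DegenerateFit(HpacircError):
    """Cosinor design matrix is rank-deficient (aliased sampling, too few points)."""


class WindowOutOfRange(HpacircError):
    """Requested AUC window is not contained in the trajectory support."""


class EmptySubspaceWarning(UserWarning):
    """Accept–reject sampling retained zero parameter triples."""


class DegenerateGeometry(HpacircError):
    """Fewer than 3 non-collinear points: no surface area is defined."""


class ZeroVariance(HpacircError):
    """Pooled responses are all equal; z-scoring is undefined."""


class NoResync(HpacircError):
    """Re-synchronization criterion unmet within the day cap."""


class IllConditioned(HpacircError):
    """Monodromy matrix condition number exceeds the trust threshold."""


class RankDeficient(HpacircError):
    """Regression design matrix is rank-deficient."""


class InsufficientPoints(HpacircError):
    """Too few accepted triples for the requested selection."""
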