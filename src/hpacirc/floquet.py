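"""Floquet stability of the periodic orbit and its parametric dependence.

The monodromy matrix is built by integrating the variational system
dPhi/dt = J(y(t)) Phi alongside the orbit over one period, using the
analytic Jacobian.  Its eigenvalues (Floquet multipliers) determine the
relaxation of amplitude perturbations; the leading exponent
log(multiplier)/period with the largest real part governs how fast the
rhythm is restored after an acute perturbation (more negative = faster
relaxation = a more rigid oscillator).  For an autonomous orbit (constant
darkness) one multiplier is trivially 1 (phase shifts along the orbit) and
is excluded from the leading exponent.

A generic monodromy integrator over user-supplied ``f``/``jac`` callables is
included for benchmark oscillators with closed-form exponents.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import statsmodels.api as sm

from ._kernels import DT_MAX, integrate_variational
from .errors import IllConditioned, RankDeficient
from .params import LightSchedule, ModelParameters
from .simulate import integrate_to_limit_cycle

__all__ = [
    "FloquetResult",
    "RegressionFit",
    "floquet_exponents",
    "monodromy_matrix",
    "floquet_from_monodromy",
    "regress_exponent_on_params",
]


@dataclass(frozen=True)
class FloquetResult:
    multipliers: np.ndarray  # complex spectrum of the monodromy matrix
    exponents: np.ndarray  # log(multipliers) / period (1/h)
    leading_exponent: float  # largest real part (trivial one excluded if autonomous)
    period: float
    autonomous: bool
    trivial_error: float  # |multiplier closest to 1| - 1, autonomous case
    condition_number: float
    ill_conditioned: bool


def floquet_from_monodromy(
    M: np.ndarray,
    period: float,
    autonomous: bool,
    cond_threshold: float = 1e40,
) -> FloquetResult:
    """Spectrum, exponents and leading exponent from a monodromy matrix."""
    if not np.all(np.isfinite(M)):
        raise IllConditioned("monodromy matrix contains non-finite entries")
    # Strong contraction along the photic directions makes cond(M) of order
    # 1e20-1e30 for perfectly healthy orbits; only far larger values signal
    # that the dominant multipliers themselves are untrustworthy.
    cond = float(np.linalg.cond(M))
    mult = np.linalg.eigvals(M)
    with np.errstate(divide="ignore", invalid="ignore"):
        expo = np.log(mult.astype(complex)) / period
    order = np.argsort(-expo.real)
    mult, expo = mult[order], expo[order]
    trivial_error = np.nan
    if autonomous:
        i_triv = int(np.argmin(np.abs(mult - 1.0)))
        trivial_error = float(np.abs(mult[i_triv]) - 1.0)
        keep = np.ones(len(mult), dtype=bool)
        keep[i_triv] = False
        leading = float(expo[keep].real.max())
    else:
        leading = float(expo.real.max())
    return FloquetResult(
        multipliers=mult,
        exponents=expo,
        leading_exponent=leading,
        period=period,
        autonomous=autonomous,
        trivial_error=trivial_error,
        condition_number=cond,
        ill_conditioned=cond > cond_threshold,
    )


def floquet_exponents(
    p: ModelParameters,
    schedule: LightSchedule | None = None,
    transient_days: int = 40,
    tol: float = 1e-5,
    dt_max: float = DT_MAX,
    y0: np.ndarray | None = None,
) -> FloquetResult:
    """Floquet spectrum of the model's converged periodic orbit.

    Under a light schedule the orbit has the schedule period and the system
    is non-autonomous (all multipliers count); with ``schedule.strength == 0``
    the free-running orbit is autonomous and the trivial unit multiplier is
    excluded from the leading exponent.
    """
    schedule = schedule or LightSchedule()
    autonomous = schedule.strength == 0.0
    cyc = integrate_to_limit_cycle(
        p, schedule, transient_days=transient_days, tol=tol, y0=y0
    )
    period = float(cyc.period)
    t0 = float(cyc.times[0])
    edges, lights = schedule.segments(t0, t0 + period)
    _, M = integrate_variational(
        np.asarray(cyc.states[0], dtype=float), p.to_array(), edges, lights, dt_max
    )
    return floquet_from_monodromy(M, period, autonomous)


def monodromy_matrix(
    f: Callable[[float, np.ndarray], np.ndarray],
    jac: Callable[[float, np.ndarray], np.ndarray],
    y0: np.ndarray,
    period: float,
    dt: float = 1e-3,
) -> np.ndarray:
    """Generic fixed-step RK4 monodromy integrator for benchmark systems.

    Integrates the state and the fundamental matrix over one period of the
    orbit through ``y0``.
    """
    y = np.asarray(y0, dtype=float).copy()
    n = len(y)
    M = np.eye(n)
    nstep = int(np.ceil(period / dt))
    h = period / nstep
    t = 0.0
    for _ in range(nstep):
        k1, m1 = f(t, y), jac(t, y) @ M
        y2 = y + 0.5 * h * k1
        k2, m2 = f(t + 0.5 * h, y2), jac(t + 0.5 * h, y2) @ (M + 0.5 * h * m1)
        y3 = y + 0.5 * h * k2
        k3, m3 = f(t + 0.5 * h, y3), jac(t + 0.5 * h, y3) @ (M + 0.5 * h * m2)
        y4 = y + h * k3
        k4, m4 = f(t + h, y4), jac(t + h, y4) @ (M + h * m3)
        y = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        M = M + h / 6.0 * (m1 + 2 * m2 + 2 * m3 + m4)
        t += h
    return M


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of leading Floquet exponents on (K_p1, K_p2, k_p3)."""

    coefficients: np.ndarray  # (b0, b1, b2, b3): intercept, K_p1, K_p2, k_p3
    r_squared: float
    residuals: np.ndarray

    @property
    def b3(self) -> float:
        """Coefficient on adrenal sensitivity k_p3."""
        return float(self.coefficients[3])


def regress_exponent_on_params(
    triples: np.ndarray, exponents: np.ndarray
) -> RegressionFit:
    """Multiple linear regression of leading exponents on the three
    regulatory parameters."""
    X = np.asarray(triples, dtype=float)
    y = np.asarray(exponents, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or len(X) != len(y):
        raise ValueError("triples must be (n, 3) matching exponents")
    if len(y) < 5:
        raise ValueError("need at least 5 triples")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < 4:
        raise RankDeficient("regression design matrix is rank-deficient")
    res = sm.OLS(y, design).fit()
    return RegressionFit(
        coefficients=np.asarray(res.params, dtype=float),
        r_squared=float(res.rsquared),
        residuals=np.asarray(res.resid, dtype=float),
    )
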