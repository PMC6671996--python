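"""Right-hand side of the coupled photic + HPA + GR model, and flux audits.

The hormonal cascade is a Goodwin-type limit-cycle oscillator: CRH drives
ACTH, ACTH drives corticosterone (CORT), and CORT closes the loop through
the glucocorticoid receptor.  Bound receptor translocates to the nucleus
(DR(N)) where it represses CRH release, ACTH release and GR transcription.
Light couples in through two 3-compartment transfer chains feeding a delayed
``light_effect`` signal that enhances CRH degradation (the photic inhibition
appropriate for a nocturnal animal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _kernels
from .params import N_STATE, STATE_NAMES, LightSchedule, ModelParameters

__all__ = [
    "light_signal",
    "rhs",
    "jacobian",
    "conservation_audit",
    "ConservationReport",
]


def light_signal(t: float, schedule: LightSchedule) -> int:
    """Square-wave photic input: 1 during the lit interval active at ``t``.

    Overrides in the schedule (inversions, delays) are honoured.  The
    entrainer ``strength`` does not affect this 0/1 signal; it scales the
    input inside :func:`rhs`.
    """
    if t < 0:
        raise ValueError("time must be nonnegative")
    return 1 if schedule.is_lit(t) else 0


def _validate(y: np.ndarray, p: ModelParameters) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape != (N_STATE,):
        raise ValueError(f"state must have shape ({N_STATE},), got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite components")
    return y


def rhs(
    t: float,
    y: np.ndarray,
    p: ModelParameters,
    schedule: LightSchedule,
) -> np.ndarray:
    """Time-derivatives of all 14 state variables at time ``t``.

    Thin validated wrapper over the compiled kernel; suitable as the
    ``fun`` argument of :func:`scipy.integrate.solve_ivp` via
    ``lambda t, y: rhs(t, y, p, schedule)``.
    """
    y = _validate(y, p)
    out = np.empty(N_STATE)
    _kernels.rhs(y, p.to_array(), schedule.light_value(t), out)
    return out


def jacobian(
    t: float,
    y: np.ndarray,
    p: ModelParameters,
    schedule: LightSchedule,
) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs` with respect to the state."""
    y = _validate(y, p)
    J = np.empty((N_STATE, N_STATE))
    _kernels.jac(y, p.to_array(), J)
    return J


# --- receptor-flux conservation audit -------------------------------------

_I = {name: i for i, name in enumerate(STATE_NAMES)}


@dataclass
class ConservationReport:
    """Outcome of the receptor flux-balance audit.

    Each entry maps a named identity to the maximum absolute residual over
    the probe states; ``mismatches`` lists identities whose residual exceeds
    the tolerance.
    """

    residuals: dict[str, float] = field(default_factory=dict)
    mismatches: list[str] = field(default_factory=list)
    tol: float = 1e-9

    @property
    def balanced(self) -> bool:
        return not self.mismatches


def conservation_audit(
    p: ModelParameters,
    rhs_func: Callable[[np.ndarray], np.ndarray] | None = None,
    probe_states: Sequence[np.ndarray] | None = None,
    tol: float = 1e-9,
) -> ConservationReport:
    """Verify that receptor fluxes are consistent across the GR equations.

    Three term-wise identities must hold for any state:

    * ``binding``: the CORT-GR binding flux leaving free GR equals the flux
      entering the cytosolic complex DR, so
      ``dDR/dt + k_T*DR == k_on*CORT*GR``.
    * ``translocation``: the nuclear translocation flux leaving DR equals
      the flux entering DR(N), so
      ``dDRN/dt + r_f*k_re*DRN == k_T*DR``.
    * ``pool``: summing the three receptor equations, the total receptor
      pool GR+DR+DR(N) changes only through synthesis and free-GR
      degradation: ``d(GR+DR+DRN)/dt == k_syn_GR*GR_mRNA - k_deg_GR*GR``.

    ``rhs_func`` may supply an alternative right-hand side (state -> state
    derivative) to audit, e.g. a deliberately broken variant in tests; the
    default audits this package's model in constant darkness (photic terms
    do not enter the receptor equations).
    """
    if rhs_func is None:
        dark = LightSchedule(strength=0.0)

        def rhs_func(y: np.ndarray) -> np.ndarray:
            return rhs(0.0, y, p, dark)

    if probe_states is None:
        rng = np.random.default_rng(1234)
        probe_states = [rng.uniform(0.05, 2.0, size=N_STATE) for _ in range(8)]

    report = ConservationReport(tol=tol)
    names = ("binding", "translocation", "pool")
    maxres = dict.fromkeys(names, 0.0)
    for y in probe_states:
        y = np.asarray(y, dtype=float)
        dy = rhs_func(y)
        cort, gr = y[_I["CORT"]], y[_I["GR"]]
        dr, drn = y[_I["DR"]], y[_I["DRN"]]
        grm = y[_I["GR_mRNA"]]
        binding = p.k_on * cort * gr
        res = {
            "binding": dy[_I["DR"]] + p.k_T * dr - binding,
            "translocation": dy[_I["DRN"]] + p.r_f * p.k_re * drn - p.k_T * dr,
            "pool": (
                dy[_I["GR"]] + dy[_I["DR"]] + dy[_I["DRN"]]
                - (p.k_syn_GR * grm - p.k_deg_GR * gr)
            ),
        }
        for k, v in res.items():
            maxres[k] = max(maxres[k], abs(float(v)))
    report.residuals = maxres
    report.mismatches = [k for k in names if maxres[k] > tol]
    return report
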