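"""In-silico experimental protocols on calibrated parameter sets.

Three protocols probe the functional consequences of regulatory variability
and allostatic adaptation:

* an acute stressor — a transient multiplicative increase of the CRH drive
  ``k_p1`` — scored by the CORT area-under-curve difference over 4 h from
  stressor onset between matched stressed and unstressed trajectories;
* a transient 96 h inversion of the light/dark schedule (shift work),
  scored by the maximum circadian phase shift of the CORT peak relative to
  an unperturbed twin;
* a permanent 10 h delay of lights-on at constant photoperiod (jet lag),
  scored by the number of days until consecutive CORT peaks are again
  spaced within 3 minutes of the schedule period.

Pooled acute-stress responses are z-scored and mapped to the five
equiprobable symbols of a symbolic-aggregate representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import NoResync, ZeroVariance
from .params import LightSchedule, ModelParameters
from .simulate import (
    OUTPUT_DT,
    Trajectory,
    auc,
    integrate,
    integrate_to_limit_cycle,
    peak_times,
)

__all__ = [
    "AcuteStressor",
    "acute_stress_response",
    "symbolize",
    "transient_inversion_phase_shift",
    "resynchronization_time",
    "SYMBOL_BREAKPOINTS",
]

#: Standard-normal quintile breakpoints Phi^-1(0.2 k), k = 1..4, delimiting
#: five equiprobable regions.
SYMBOL_BREAKPOINTS = norm.ppf([0.2, 0.4, 0.6, 0.8])


@dataclass(frozen=True)
class AcuteStressor:
    """A transient pulse in CRH synthesis drive.

    ``onset`` is clock time (h); during [onset, onset + duration] the
    zero-order CRH synthesis rate k_p1 is multiplied by ``fold_increase``.
    """

    onset: float = 14.0  # mid lights-on: middle of the inactive phase
    duration: float = 1.0
    fold_increase: float = 5.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.fold_increase < 1:
            raise ValueError("fold_increase must be >= 1")


def acute_stress_response(
    p: ModelParameters,
    stressor: AcuteStressor,
    schedule: LightSchedule | None = None,
    window: float = 4.0,
    transient_days: int = 30,
    tol: float = 1e-4,
    y0: np.ndarray | None = None,
) -> float:
    """CORT AUC difference (stressed - unstressed) over ``window`` h from onset.

    Both trajectories start from the identical converged entrained-cycle
    state at stressor onset, so the difference isolates the stressor.
    """
    schedule = schedule or LightSchedule()
    cyc = integrate_to_limit_cycle(
        p, schedule, transient_days=transient_days, tol=tol, y0=y0
    )
    t0 = cyc.times[0]
    onset = t0 + (stressor.onset - t0) % schedule.period
    # state at onset, from the converged cycle start
    at_onset = integrate(p, schedule, t0, onset, y0=cyc.states[0], output_dt=None)
    y_on = at_onset.final_state

    control = integrate(p, schedule, onset, onset + window, y0=y_on)
    p_stress = p.replace(k_p1=p.k_p1 * stressor.fold_increase)
    t_off = onset + min(stressor.duration, window)
    pulse = integrate(p_stress, schedule, onset, t_off, y0=y_on)
    if t_off < onset + window:
        tail = integrate(
            p, schedule, t_off, onset + window, y0=pulse.final_state
        )
        times = np.concatenate([pulse.times, tail.times[1:]])
        states = np.concatenate([pulse.states, tail.states[1:]])
    else:
        times, states = pulse.times, pulse.states
    stressed = Trajectory(
        times=times, states=states, schedule=schedule, params=p_stress
    )
    return auc(stressed, onset, window) - auc(control, onset, window)


def symbolize(delta_aucs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """z-score a pooled response population and assign quintile symbols 1-5.

    The breakpoints are the standard-normal quintiles (+/-0.8416, +/-0.2533),
    so symbols are equiprobable for normally distributed responses; symbol 1
    is the lower tail, symbol 5 the upper.  Returns ``(z, symbols)``.
    """
    x = np.asarray(delta_aucs, dtype=float)
    if x.size < 5:
        raise ValueError("need a pooled population of at least 5 responses")
    sd = float(x.std(ddof=0))
    if sd == 0.0:
        raise ZeroVariance("all pooled responses are equal")
    z = (x - x.mean()) / sd
    symbols = 1 + np.searchsorted(SYMBOL_BREAKPOINTS, z)
    return z, symbols.astype(int)


def _daily_peak_phases(
    traj_times: np.ndarray, cort: np.ndarray, period: float
) -> tuple[np.ndarray, np.ndarray]:
    """(day index, peak phase mod period) for each detected CORT peak."""
    pk = peak_times(traj_times, cort)
    days = np.floor(pk / period).astype(int)
    return days, pk % period


def _circ_diff(a: float, b: float, period: float) -> float:
    d = (a - b) % period
    return d - period if d > period / 2 else d


def transient_inversion_phase_shift(
    p: ModelParameters,
    base: LightSchedule | None = None,
    inversion_hours: float = 96.0,
    transient_days: int = 40,
    follow_days: int = 16,
    tol: float = 1e-4,
    y0: np.ndarray | None = None,
) -> float:
    """Maximum circadian CORT phase shift caused by a transient inversion.

    The light/dark schedule is inverted for ``inversion_hours`` (default
    96 h, i.e. 4 full days starting at midnight of the first perturbed day)
    and then restored; an unperturbed twin acts as control.  Returns the
    maximum over post-inversion days of the circular difference between
    twin CORT peak phases, in hours within [0, period/2].
    """
    base = base or LightSchedule()
    period = base.period
    if inversion_hours < 0:
        raise ValueError("inversion_hours must be nonnegative")
    cyc = integrate_to_limit_cycle(
        p, base, transient_days=transient_days, tol=tol, y0=y0
    )
    y_start = cyc.states[0]
    n_inv_days = int(np.ceil(inversion_hours / period))
    d0 = 1  # perturbation starts at midnight of day 1 of the follow-up run
    inv = base.with_overrides((d0, d0 + n_inv_days, base.lights_off, base.lights_on))
    horizon = (d0 + n_inv_days + follow_days) * period
    ctrl = integrate(p, base, 0.0, horizon, y0=y_start, output_dt=OUTPUT_DT)
    pert = integrate(p, inv, 0.0, horizon, y0=y_start, output_dt=OUTPUT_DT)
    if inversion_hours == 0:
        return 0.0
    days_c, ph_c = _daily_peak_phases(ctrl.times, ctrl.cort, period)
    days_p, ph_p = _daily_peak_phases(pert.times, pert.cort, period)
    shift = 0.0
    for day in range(d0, d0 + n_inv_days + follow_days):
        mc = days_c == day
        mp = days_p == day
        if mc.sum() != 1 or mp.sum() != 1:
            continue  # skip days without a unique peak in either twin
        d = abs(_circ_diff(float(ph_p[mp][0]), float(ph_c[mc][0]), period))
        shift = max(shift, d)
    return shift


def resynchronization_time(
    p: ModelParameters,
    base: LightSchedule | None = None,
    delay_h: float = 10.0,
    criterion_h: float = 0.05,
    n_consecutive: int = 3,
    transient_days: int = 40,
    max_days: int = 60,
    tol: float = 1e-4,
    y0: np.ndarray | None = None,
) -> int:
    """Days to re-entrain after a permanent delay of lights-on.

    From the day of the shift, lights-on is delayed by ``delay_h`` (default
    10 h, moving 07:00 to 17:00) at constant photoperiod.  The system is
    re-synchronized on the first day from which the spacing of consecutive
    CORT peaks stays within ``criterion_h`` (3 min) of the schedule period
    for ``n_consecutive`` cycles.  Returns the day index relative to the
    shift day (0 = already synchronized on the shift day).
    """
    base = base or LightSchedule()
    period = base.period
    if not 0 <= delay_h < period:
        raise ValueError("delay_h must lie in [0, period)")
    cyc = integrate_to_limit_cycle(
        p, base, transient_days=transient_days, tol=tol, y0=y0
    )
    if delay_h == 0:
        return 0
    y_start = cyc.states[0]
    new_on = (base.lights_on + delay_h) % period
    new_off = (base.lights_off + delay_h) % period
    d0 = 1
    shifted = base.with_overrides((d0, np.inf, new_on, new_off))
    horizon = (d0 + max_days) * period
    traj = integrate(p, shifted, 0.0, horizon, y0=y_start, output_dt=OUTPUT_DT)
    pk = peak_times(traj.times, traj.cort)
    pk = pk[pk >= d0 * period]
    spacing = np.diff(pk)
    ok = np.abs(spacing - period) <= criterion_h
    for i in range(len(ok) - n_consecutive + 1):
        if np.all(ok[i : i + n_consecutive]):
            day = int(np.floor((pk[i] - d0 * period) / period))
            return max(day, 0)
    raise NoResync(
        f"not re-synchronized within {max_days} days of the {delay_h} h delay"
    )
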