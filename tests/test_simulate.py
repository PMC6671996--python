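"""Limit-cycle integration and trajectory feature extraction."""

import numpy as np
import pytest

import hpacirc as h
from hpacirc.errors import WindowOutOfRange
from hpacirc.params import N_STATE
from hpacirc.simulate import (
    OUTPUT_DT,
    Trajectory,
    auc,
    cort_peak_phase,
    integrate,
    integrate_to_limit_cycle,
    peak_times,
)


def _fake_trajectory(times, cort, schedule, params, period=24.0):
    states = np.zeros((len(times), N_STATE))
    states[:, 9] = cort
    return Trajectory(
        times=times, states=states, schedule=schedule, params=params, period=period
    )


class TestLimitCycle:
    def test_entrained_period_is_schedule_period(self, entrained_cycle):
        """Peak-to-peak interval on the converged cycle equals 24 h within
        1e-3 h (checked on a two-cycle continuation)."""
        cyc = entrained_cycle
        assert cyc.period == 24.0
        two = integrate(
            cyc.params,
            cyc.schedule,
            cyc.times[0],
            cyc.times[0] + 48.0,
            y0=cyc.states[0],
            output_dt=0.01,
        )
        pk = peak_times(two.times, two.cort)
        assert len(pk) == 2
        assert np.diff(pk)[0] == pytest.approx(24.0, abs=1e-3)

    def test_free_running_period_differs_from_24(self, params, dark_schedule):
        cyc = integrate_to_limit_cycle(
            params, dark_schedule, transient_days=60, tol=1e-3
        )
        assert cyc.period is not None
        assert abs(cyc.period - 24.0) > 0.5  # tau != 24 in constant darkness
        assert 18.0 < cyc.period < 28.0

    def test_infinite_tol_returns_after_transient(self, params, schedule):
        traj = integrate_to_limit_cycle(
            params, schedule, transient_days=3, tol=np.inf
        )
        assert traj.times[0] == pytest.approx(3 * 24.0)
        assert traj.times[-1] == pytest.approx(4 * 24.0)

    def test_two_initializations_reach_same_cycle(self, params, schedule, entrained_cycle):
        """The entrained attractor is reached from a different nonnegative
        initial condition (uniqueness asserted, not proven)."""
        rng = np.random.default_rng(11)
        y0 = rng.uniform(0.05, 1.0, N_STATE)
        y0[:7] = 0.0
        other = integrate_to_limit_cycle(
            params, schedule, transient_days=40, y0=y0
        )
        amp = 0.5 * np.ptp(entrained_cycle.cort)
        assert np.max(np.abs(other.cort - entrained_cycle.cort)) / amp < 1e-3

    def test_solver_robustness_step_halving(self, params, schedule):
        """Halving the RK4 step changes the converged CORT cycle by far less
        than the convergence tolerance."""
        a = integrate_to_limit_cycle(params, schedule, transient_days=30, dt_max=0.02)
        b = integrate_to_limit_cycle(params, schedule, transient_days=30, dt_max=0.01)
        amp = 0.5 * np.ptp(a.cort)
        assert np.max(np.abs(a.cort - b.cort)) / amp < 1e-5


class TestPeakPhase:
    def test_synthetic_cosine_peak_recovered(self, params, schedule):
        """A pure cosine with acrophase 20:00 must yield peak time 20:00."""
        t = np.arange(0.0, 24.0 + 1e-9, OUTPUT_DT)
        c = 5.0 + 2.0 * np.cos(2 * np.pi * (t - 20.0) / 24.0)
        traj = _fake_trajectory(t, c, schedule, params)
        assert cort_peak_phase(traj) == pytest.approx(20.0, abs=OUTPUT_DT / 2)

    def test_grid_refinement_agreement(self, entrained_cycle):
        """Peak times from 0.1 h and 0.01 h sampling of the same solution
        agree within 0.05 h."""
        cyc = entrained_cycle
        res = {}
        for dt in (0.1, 0.01):
            traj = integrate(
                cyc.params,
                cyc.schedule,
                cyc.times[0],
                cyc.times[0] + 24.0,
                y0=cyc.states[0],
                output_dt=dt,
            )
            res[dt] = cort_peak_phase(traj)
        assert abs(res[0.1] - res[0.01]) < 0.05

    def test_time_shift_equivariance(self, entrained_cycle):
        shifted = entrained_cycle.shifted(3.0)
        a = cort_peak_phase(entrained_cycle)
        b = cort_peak_phase(shifted)
        assert (b - a) % 24.0 == pytest.approx(3.0, abs=1e-9)

    def test_constant_signal_raises(self, params, schedule):
        t = np.arange(0.0, 25.0, 0.5)
        traj = _fake_trajectory(t, np.full_like(t, 2.0), schedule, params)
        with pytest.raises(ValueError):
            cort_peak_phase(traj)


class TestAuc:
    def test_constant_signal_rectangle(self, params, schedule):
        t = np.arange(0.0, 25.0, 0.5)
        traj = _fake_trajectory(t, np.full_like(t, 3.0), schedule, params)
        assert auc(traj, 2.0, 4.0) == pytest.approx(12.0)

    def test_linear_ramp_exact(self, params, schedule):
        t = np.arange(0.0, 25.0, 0.5)
        traj = _fake_trajectory(t, 1.0 + 0.5 * t, schedule, params)
        # integral of 1 + 0.5 t over [3, 7] = 4 + 0.25*(49-9)
        assert auc(traj, 3.0, 4.0) == pytest.approx(14.0)

    def test_sampling_refinement(self, entrained_cycle):
        """Halving the output step changes the AUC of the smooth model
        trajectory by < 1e-4 relative."""
        cyc = entrained_cycle
        vals = {}
        for dt in (0.05, 0.025):
            traj = integrate(
                cyc.params,
                cyc.schedule,
                cyc.times[0],
                cyc.times[0] + 24.0,
                y0=cyc.states[0],
                output_dt=dt,
            )
            vals[dt] = auc(traj, cyc.times[0] + 2.0, 4.0)
        assert abs(vals[0.05] - vals[0.025]) / vals[0.025] < 1e-4

    def test_window_outside_support_raises(self, params, schedule):
        t = np.arange(0.0, 24.1, 0.5)
        traj = _fake_trajectory(t, np.ones_like(t), schedule, params)
        with pytest.raises(WindowOutOfRange):
            auc(traj, 22.0, 4.0)


def test_trajectory_tidy_export(entrained_cycle):
    df = entrained_cycle.to_frame()
    assert set(df.columns) == {"time", "variable", "value"}
    assert len(df) == len(entrained_cycle.times) * N_STATE
    cort = df[df.variable == "CORT"].value.to_numpy()
    assert np.array_equal(cort, entrained_cycle.cort)


def test_cycle_features_summarize_the_converged_cycle(entrained_cycle):
    from hpacirc.simulate import cycle_features

    f = cycle_features(entrained_cycle)
    assert f.period == 24.0
    assert f.amplitude == pytest.approx(0.5 * np.ptp(entrained_cycle.cort))
    assert 0.0 <= f.peak_time < 24.0 and 0.0 <= f.trough_time < 24.0
    assert f.peak_time != f.trough_time
    assert f.mean > 0
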