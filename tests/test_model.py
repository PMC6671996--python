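"""Right-hand side, Jacobian and flux-conservation checks."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import hpacirc as h
from hpacirc.params import N_STATE, STATE_NAMES
from hpacirc.simulate import default_initial_state, integrate

I = {name: i for i, name in enumerate(STATE_NAMES)}


def test_light_signal_follows_schedule(schedule):
    assert h.light_signal(12.0, schedule) == 1
    assert h.light_signal(22.0, schedule) == 0
    inverted = h.LightSchedule(lights_on=21.0, lights_off=7.0)
    assert h.light_signal(12.0, inverted) == 0


def test_rhs_at_zero_state_is_pure_crh_drive(params, schedule):
    """At the all-zero state the only nonzero hormonal derivative is the
    zero-order CRH synthesis k_p1 (feedback factor 1, degradation 0)."""
    dy = h.rhs(2.0, np.zeros(N_STATE), params, h.LightSchedule(strength=0.0))
    assert dy[I["CRH"]] == pytest.approx(params.k_p1)
    assert dy[I["GR_mRNA"]] == pytest.approx(params.k_syn_GRm)  # also zero-order
    for name in ("ACTH", "CORT", "DR", "DRN"):
        assert dy[I[name]] == 0.0


def test_rhs_rejects_bad_state(params, schedule):
    with pytest.raises(ValueError):
        h.rhs(0.0, np.full(N_STATE, np.nan), params, schedule)
    with pytest.raises(ValueError):
        h.rhs(0.0, np.zeros(3), params, schedule)


def test_constant_light_photic_fixed_point(params):
    """Under permanent light the transfer chains converge to 1 and the
    light_effect converges to the algebraic balance of its Hill synthesis
    against its (chain-enhanced) degradation."""
    always_on = h.LightSchedule(lights_on=0.0, lights_off=23.999999)
    traj = integrate(params, always_on, 0.0, 400.0, output_dt=None)
    y = traj.final_state
    for name in ("light_TCsynth3", "light_TCdeg3"):
        assert y[I[name]] == pytest.approx(1.0, abs=1e-6)
    hill = 1.0 / (params.K_M_us**params.n + 1.0)
    le_star = params.k_us * hill / (params.k_deg_us * (1.0 + params.k_eff))
    assert y[I["light_effect"]] == pytest.approx(le_star, rel=1e-6)


def test_recycling_terms_vanish_at_rf_zero(params, schedule):
    """With r_f = 0 the DR(N) efflux disappears: dDRN/dt collapses to the
    pure translocation influx k_T * DR, and dGR/dt loses the recycling term."""
    p0 = params.replace(r_f=0.0)
    rng = np.random.default_rng(7)
    y = rng.uniform(0.1, 1.5, N_STATE)
    dy = h.rhs(0.0, y, p0, h.LightSchedule(strength=0.0))
    assert dy[I["DRN"]] == pytest.approx(p0.k_T * y[I["DR"]])
    expected_gr = (
        p0.k_syn_GR * y[I["GR_mRNA"]]
        - p0.k_on * y[I["CORT"]] * y[I["GR"]]
        - p0.k_deg_GR * y[I["GR"]]
    )
    assert dy[I["GR"]] == pytest.approx(expected_gr)


def test_jacobian_matches_finite_differences(params, schedule):
    rng = np.random.default_rng(3)
    y = rng.uniform(0.05, 1.5, N_STATE)
    J = h.jacobian(9.5, y, params, schedule)
    eps = 1e-7
    for j in range(N_STATE):
        e = np.zeros(N_STATE)
        e[j] = eps
        fd = (h.rhs(9.5, y + e, params, schedule) - h.rhs(9.5, y - e, params, schedule)) / (
            2 * eps
        )
        assert np.allclose(J[:, j], fd, rtol=1e-5, atol=1e-6), f"column {j}"


def test_kernel_agrees_with_scipy_reference(params, schedule):
    """The fixed-step RK4 kernel and scipy's adaptive LSODA agree on a
    5-day light-driven trajectory from standard initial conditions."""
    y0 = default_initial_state()
    ours = integrate(params, schedule, 0.0, 120.0, y0=y0, output_dt=None).final_state

    edges, lights = schedule.segments(0.0, 120.0)
    y = y0.copy()
    for k in range(len(lights)):
        lit = h.LightSchedule() if lights[k] else h.LightSchedule(strength=0.0)
        sol = solve_ivp(
            lambda t, yy: h.rhs(t, yy, params, lit),
            (edges[k], edges[k + 1]),
            y,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        y = sol.y[:, -1]
    assert np.allclose(ours, y, rtol=1e-6, atol=1e-9)


def test_nonnegativity_over_thirty_days(params, schedule):
    """No state component goes below -(solver tolerance) over >= 30 days
    from nonnegative initial conditions."""
    traj = integrate(params, schedule, 0.0, 31 * 24.0, output_dt=0.05)
    assert traj.states.min() > -1e-9


def test_dark_photic_subsystem_stays_zero_and_shift_invariant(params):
    """In constant darkness the photic cascade remains identically zero and
    the autonomous dynamics are invariant to shifting the initial clock
    instant."""
    dark = h.LightSchedule(strength=0.0)
    y0 = default_initial_state()
    a = integrate(params, dark, 0.0, 100.0, y0=y0, output_dt=1.0)
    assert np.abs(a.states[:, :7]).max() == 0.0
    b = integrate(params, dark, 13.0, 113.0, y0=y0, output_dt=1.0)
    assert np.allclose(a.states, b.states, rtol=1e-9, atol=1e-12)


def test_frozen_drn_crh_reaches_michaelis_menten_steady_state(params):
    """With DR(N) frozen at zero in darkness, CRH follows zero-order
    production minus Michaelis-Menten loss; the long-run level matches the
    closed form of k_p1 = V_d1 * CRH / (K_d1 + CRH) to 1e-6 relative."""
    p = params.replace(k_p1=0.5)  # production below V_d1 so a balance exists
    assert p.k_p1 < p.V_d1
    crh_star = p.k_p1 * p.K_d1 / (p.V_d1 - p.k_p1)
    dark = h.LightSchedule(strength=0.0)

    def frozen(t, y):
        dy = h.rhs(t, y, p, dark)
        dy[I["DRN"]] = 0.0
        return dy

    y0 = default_initial_state()
    y0[I["DRN"]] = 0.0
    sol = solve_ivp(frozen, (0.0, 400.0), y0, method="LSODA", rtol=1e-10, atol=1e-12)
    assert sol.y[I["CRH"], -1] == pytest.approx(crh_star, rel=1e-6)


class TestConservationAudit:
    def test_default_model_is_balanced(self, params):
        rep = h.conservation_audit(params)
        assert rep.balanced
        assert set(rep.residuals) == {"binding", "translocation", "pool"}

    def test_constructed_violation_is_flagged(self, params):
        """A right-hand side whose DR equation uses a perturbed k_T (not
        matching the DR(N) influx) must be caught."""
        dark = h.LightSchedule(strength=0.0)

        def broken(y):
            dy = h.rhs(0.0, y, params, dark)
            dy[I["DR"]] = params.k_on * y[I["CORT"]] * y[I["GR"]] - 1.37 * params.k_T * y[
                I["DR"]
            ]
            return dy

        rep = h.conservation_audit(params, rhs_func=broken)
        assert not rep.balanced
        assert "binding" in rep.mismatches

    def test_full_recycling_returns_all_efflux(self, params):
        """At r_f = 1 the DR(N) efflux k_re * DRN re-enters GR entirely."""
        p1 = params.replace(r_f=1.0)
        rep = h.conservation_audit(p1)
        assert rep.balanced
        y = np.full(N_STATE, 0.5)
        dy = h.rhs(0.0, y, p1, h.LightSchedule(strength=0.0))
        gr_gain_from_recycling = p1.k_re * y[I["DRN"]]
        without = (
            p1.k_syn_GR * y[I["GR_mRNA"]]
            - p1.k_on * y[I["CORT"]] * y[I["GR"]]
            - p1.k_deg_GR * y[I["GR"]]
        )
        assert dy[I["GR"]] == pytest.approx(without + gr_gain_from_recycling)
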