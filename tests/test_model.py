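"""Unit and property tests for the compartment model and its integrator."""

import numpy as np
import pytest

import gliotmz as g
from gliotmz.model import InvalidInputError


class TestActivationRate:
    def test_midpoint_is_half_amplitude(self, default_params):
        assert g.activation_rate(0.01, default_params) == pytest.approx(7.5)

    def test_saturates_to_zero_at_full_effect(self, default_params):
        assert g.activation_rate(1.0, default_params) < 1e-10

    def test_value_at_zero_drug(self, default_params):
        # 7.5 * (1 + tanh(1)), evaluated independently
        assert g.activation_rate(0.0, default_params) == pytest.approx(
            13.2119561696682, rel=1e-10
        )

    def test_negative_effect_rejected(self, default_params):
        with pytest.raises(InvalidInputError):
            g.activation_rate(-0.1, default_params)

    def test_bounded_by_twice_amplitude(self, default_params):
        e = np.linspace(0.0, 2.0, 101)
        f = g.activation_rate(e, default_params)
        assert np.all(f >= 0.0) and np.all(f <= 2 * default_params.f_scale)


class TestDerivatives:
    def test_pure_sensitive_growth_without_drug(self, default_params):
        state = g.SystemState(V_S=1.0)
        d = g.derivatives(state, default_params)
        assert d[0] == pytest.approx(default_params.rho1)
        assert d[1] == d[3] == d[4] == 0.0
        assert d[2] == 0.0

    def test_mass_balance_of_transfer_terms(self):
        # sum of volume derivatives must equal rho1*V_S - tau*V_D + rho2*V_R
        p = g.ModelParams(rho1=0.1, rho2=0.2, psi=0.4, alpha1=0.3, alpha2=0.05,
                          tau=0.05)
        state = g.SystemState(V_S=2.0, V_D=1.0, V_R=3.0)
        d = g.derivatives(state, p)
        assert d[:5].sum() == pytest.approx(0.1 * 2 + 0.2 * 3 - 0.05 * 1)

    def test_intermediate_persisters_stabilize_at_zero_drug(self, default_params):
        state = g.SystemState(V_S=0.0, V_PI=1.0)
        d = g.derivatives(state, default_params)
        f0 = g.activation_rate(0.0, default_params)
        assert d[2] == pytest.approx(-f0)
        assert d[3] == pytest.approx(f0)


class TestApplyDose:
    def test_effect_jump_volumes_unchanged(self):
        s = g.SystemState(V_S=5.3, V_D=0.2, E=0.0)
        s2 = g.apply_dose(s, 1.0)
        assert s2.E == pytest.approx(1.0)
        assert s2.V_S == 5.3 and s2.V_D == 0.2

    def test_jump_is_additive(self):
        s = g.apply_dose(g.SystemState(V_S=1.0, E=0.2), 0.5)
        assert s.E == pytest.approx(0.7)

    @pytest.mark.parametrize("e0", [0.0, -0.5, 1.5])
    def test_invalid_dose_rejected(self, e0):
        with pytest.raises(InvalidInputError):
            g.apply_dose(g.SystemState(V_S=1.0), e0)


class TestClearanceRate:
    def test_two_hour_half_life(self):
        assert g.clearance_rate(2.0) == pytest.approx(8.32, abs=5e-3)

    def test_one_day_half_life(self):
        assert g.clearance_rate(24.0) == pytest.approx(np.log(2), rel=1e-12)

    def test_scales_inversely(self):
        assert g.clearance_rate(1.0) == pytest.approx(2 * g.clearance_rate(2.0))

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidInputError):
            g.clearance_rate(0.0)


class TestSimulate:
    def test_untreated_growth_is_exponential(self, default_params):
        cfg = g.SimulationConfig(horizon=365.0, output_step=10.0)
        traj = g.simulate(default_params, 10.0, [], cfg)
        expected = 10.0 * np.exp(default_params.rho1 * traj.times)
        np.testing.assert_allclose(traj.total_volume, expected, rtol=1e-7)

    def test_drug_decouples_without_kill_or_switch_terms(self):
        # psi and alpha1 cannot be exactly zero; tiny values make the drug
        # terms negligible so volume follows the untreated trajectory
        p = g.ModelParams(rho1=1e-3, rho2=4e-3, psi=1e-14, alpha1=1e-13,
                          alpha2=1e-14, tau=3e-3)
        cfg = g.SimulationConfig(horizon=60.0, output_step=1.0)
        dosed = g.simulate(p, 10.0, [(10.0, 1.0)], cfg)
        free = g.simulate(p, 10.0, [], cfg)
        v_dosed = np.interp(np.arange(61.0), dosed.times, dosed.total_volume)
        v_free = np.interp(np.arange(61.0), free.times, free.total_volume)
        np.testing.assert_allclose(v_dosed, v_free, rtol=1e-7)
        # E follows the closed-form exponential decay after the dose
        # (compared where E is above the solver's absolute-error floor)
        post = dosed.times > 10.0
        e_expected = 1.0 * np.exp(-p.lam * (dosed.times[post] - 10.0))
        big = e_expected > 1e-6
        np.testing.assert_allclose(
            dosed.states[post, 5][big], e_expected[big], rtol=1e-5
        )

    def test_mass_conservation_with_zero_growth_and_death(self):
        # with rho1 = rho2 = tau ~ 0 the transfer terms only move volume
        # between compartments: the total is conserved across dosing
        p = g.ModelParams(rho1=1e-15, rho2=2e-15, psi=0.5, alpha1=0.35,
                          alpha2=0.06, tau=1e-15)
        cfg = g.SimulationConfig(horizon=200.0, output_step=5.0)
        traj = g.simulate(p, 10.0, g.build_c28(3), cfg)
        np.testing.assert_allclose(traj.total_volume, 10.0, rtol=1e-7)

    def test_linearity_in_initial_volume(self, default_params):
        cfg = g.SimulationConfig(horizon=400.0, output_step=10.0)
        proto = g.build_c28(4)
        t1 = g.simulate(default_params, 7.0, proto, cfg)
        t2 = g.simulate(default_params, 21.0, proto, cfg)
        np.testing.assert_allclose(3.0 * t1.states[:, :5], t2.states[:, :5],
                                   rtol=1e-7, atol=1e-8)

    def test_total_volume_continuous_at_dose_times(self, default_params):
        cfg = g.SimulationConfig(horizon=100.0, output_step=1.0)
        traj = g.simulate(default_params, 10.0, [(30.0, 1.0)], cfg)
        at_dose = np.flatnonzero(traj.times == 30.0)
        assert at_dose.size == 2
        pre, post = traj.states[at_dose[0]], traj.states[at_dose[1]]
        assert pre[:5].sum() == post[:5].sum()  # exact: the impulse moves E only
        assert post[5] - pre[5] == pytest.approx(1.0)

    def test_same_day_doses_stack_additively(self, default_params):
        cfg = g.SimulationConfig(horizon=50.0, output_step=1.0)
        traj = g.simulate(default_params, 10.0, [(20.0, 0.4), (20.0, 0.5)], cfg)
        at_dose = np.flatnonzero(traj.times == 20.0)
        assert traj.states[at_dose[-1], 5] == pytest.approx(0.9)

    def test_compartments_stay_nonnegative(self, patient3):
        cfg = g.SimulationConfig(horizon=1500.0, output_step=5.0)
        traj = g.simulate(patient3, 15.0, g.build_c28(16), cfg)
        assert traj.states.min() >= 0.0

    def test_response_then_resistant_regrowth(self, patient3):
        # cyclic treatment: decline below baseline then regrowth that the
        # resistant compartment dominates
        cfg = g.SimulationConfig(horizon=3000.0, output_step=5.0)
        traj = g.simulate(patient3, 15.0, g.build_c28(16), cfg)
        v = traj.total_volume
        assert v.min() < 15.0
        assert v[-1] > 15.0
        final = traj.states[-1]
        assert final[4] > 0.5 * final[:5].sum()

    def test_invalid_inputs_rejected(self, default_params):
        with pytest.raises(InvalidInputError):
            g.simulate(default_params, -1.0, [])
        with pytest.raises(InvalidInputError):
            g.simulate(default_params, 1.0, [(5.0, 1.0), (2.0, 1.0)])


def _rk4_reference(params, y0, dose_times, dose_e0, t_end, h):
    """Fixed-step classical Runge-Kutta reference, doses applied exactly."""
    from gliotmz._kernel import rhs

    p = params.as_vector()
    y = y0.copy()
    t = 0.0
    events = list(zip(dose_times, dose_e0)) + [(t_end, None)]
    for t_stop, e0 in events:
        n = max(1, int(round((t_stop - t) / h)))
        dt = (t_stop - t) / n
        for _ in range(n):
            k1 = rhs(y, p)
            k2 = rhs(y + 0.5 * dt * k1, p)
            k3 = rhs(y + 0.5 * dt * k2, p)
            k4 = rhs(y + dt * k3, p)
            y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = t_stop
        if e0 is not None:
            y[5] += e0
    return y


def test_adaptive_integrator_matches_fixed_step_reference(default_params):
    """30-day, 3-dose run agrees with a fine fixed-step reference."""
    dose_times = [5.0, 12.0, 19.0]
    dose_e0 = [1.0, 1.0, 1.0]
    cfg = g.SimulationConfig(horizon=30.0, output_step=30.0)
    traj = g.simulate(default_params, 10.0, list(zip(dose_times, dose_e0)), cfg)
    y_ref = _rk4_reference(
        default_params, np.array([10.0, 0, 0, 0, 0, 0.0]), dose_times, dose_e0,
        30.0, 1e-3,
    )
    v_ref = y_ref[:5].sum()
    assert traj.total_volume[-1] == pytest.approx(v_ref, rel=1e-5)


class TestModelParams:
    def test_positivity_enforced(self):
        with pytest.raises(InvalidInputError):
            g.ModelParams(rho1=0.0, rho2=1e-3, psi=0.1, alpha1=0.3,
                          alpha2=0.05, tau=1e-3)

    def test_persister_ordering_enforced(self):
        with pytest.raises(InvalidInputError):
            g.ModelParams(rho1=1e-4, rho2=1e-3, psi=0.1, alpha1=0.05,
                          alpha2=0.3, tau=1e-3)

    def test_slow_resistant_growth_warns(self):
        with pytest.warns(UserWarning):
            g.ModelParams(rho1=2e-3, rho2=1e-3, psi=0.1, alpha1=0.3,
                          alpha2=0.05, tau=1e-3)
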