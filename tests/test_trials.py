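"""Survival endpoints, KM/log-rank machinery and trial orchestration."""

import itertools

import numpy as np
import pytest

import gliotmz as g
from gliotmz.model import InvalidInputError
from gliotmz.trials import SurvivalOutcome


def _outcome(t, event=True, pid=0):
    return SurvivalOutcome(pid, float(t), bool(event))


class TestTimeToFatal:
    def test_exponential_crossing_closed_form(self):
        # no doses, growth dominated by rho1: V0*exp(rho1*t) = V_fatal
        p = g.ModelParams(rho1=1e-3, rho2=1.1e-3, psi=1e-6, alpha1=1e-5,
                          alpha2=1e-6, tau=1e-6)
        vp = g.VirtualPatient(params=p, V0=100.0, dose_budget=1, V_fatal=280.0)
        out = g.time_to_fatal(
            vp, g.build_id(7, 1, e0=1.0), g.TrialSpec(seed=0), None
        )
        # one dose with negligible kill terms barely perturbs the crossing
        expected = np.log(2.8) / 1e-3
        assert out.event
        assert out.time == pytest.approx(expected, rel=1e-3)

    def test_fatal_below_initial_is_immediate(self):
        p = g.ModelParams(rho1=1e-3, rho2=2e-3, psi=0.1, alpha1=0.3,
                          alpha2=0.05, tau=1e-3)
        vp = g.VirtualPatient(params=p, V0=300.0, dose_budget=5, V_fatal=280.0)
        out = g.time_to_fatal(vp, g.build_id(7, 5), g.TrialSpec(seed=0))
        assert out.event and out.time < 1.0

    def test_near_zero_growth_censors_at_horizon(self):
        p = g.ModelParams(rho1=1e-8, rho2=2e-8, psi=0.1, alpha1=0.05,
                          alpha2=0.01, tau=1e-3)
        vp = g.VirtualPatient(params=p, V0=10.0, dose_budget=5, V_fatal=280.0)
        spec = g.TrialSpec(seed=0, horizon=2000.0)
        out = g.time_to_fatal(vp, g.build_id(7, 5), spec)
        assert not out.event
        assert out.time == spec.horizon


def _km_oracle(outcomes):
    """Brute-force product-limit estimator at distinct event times."""
    times = sorted({o.time for o in outcomes if o.event})
    s = 1.0
    curve = []
    for t in times:
        at_risk = sum(1 for o in outcomes if o.time >= t)
        deaths = sum(1 for o in outcomes if o.event and o.time == t)
        s *= 1.0 - deaths / at_risk
        curve.append((t, s))
    return curve


def _km_survival_at(km, t):
    idx = np.searchsorted(km.times, t, side="right") - 1
    return km.survival[idx] if idx >= 0 else 1.0


class TestKaplanMeier:
    def test_three_events_no_censoring(self):
        km = g.kaplan_meier([_outcome(1), _outcome(2), _outcome(3)])
        assert _km_survival_at(km, 1) == pytest.approx(2 / 3)
        assert _km_survival_at(km, 2) == pytest.approx(1 / 3)
        assert _km_survival_at(km, 3) == pytest.approx(0.0)
        assert km.median == 2.0

    def test_all_censored_flat_curve(self):
        km = g.kaplan_meier([_outcome(5, False), _outcome(7, False)])
        assert np.all(km.survival == 1.0)
        assert np.isinf(km.median)

    def test_single_event_median(self):
        km = g.kaplan_meier([_outcome(4.5)])
        assert km.median == 4.5
        assert _km_survival_at(km, 4.5) == 0.0

    def test_matches_enumeration_oracle_on_small_inputs(self):
        """Product-limit estimate equals the brute-force oracle for every
        event/censor labelling of up to 6 outcomes."""
        time_grid = [1.0, 2.0, 2.0, 3.5, 4.0, 6.0]
        for n in (1, 2, 3, 6):
            times = time_grid[:n]
            for flags in itertools.product([True, False], repeat=n):
                outcomes = [_outcome(t, e, i)
                            for i, (t, e) in enumerate(zip(times, flags))]
                km = g.kaplan_meier(outcomes)
                for t, s in _km_oracle(outcomes):
                    assert _km_survival_at(km, t) == pytest.approx(s), (
                        times, flags, t)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            g.kaplan_meier([])


class TestLogrank:
    def test_identical_arms_give_unit_p(self):
        arm = [_outcome(t, True, i) for i, t in enumerate([1, 2, 3, 4])]
        stat, p = g.logrank_test(arm, list(arm))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_separated_arms(self):
        # events A={1,2}, B={3,4}: arm A contributes only at t=1 (at risk
        # 2+2, E_A=1/2, V=2*2*1*3/(16*3)=1/4) and t=2 (at risk 1+2,
        # E_A=1/3, V=1*2*1*2/(9*2)=2/9); at t=3,4 no A patients remain.
        # O_A-E_A = 7/6, V = 17/36, chi2 = (7/6)^2/(17/36) = 49/17
        a = [_outcome(1, True, 0), _outcome(2, True, 1)]
        b = [_outcome(3, True, 0), _outcome(4, True, 1)]
        stat, p = g.logrank_test(a, b)
        assert stat == pytest.approx(49 / 17, rel=1e-10)

    def test_symmetric_in_arm_labels(self):
        rng = np.random.default_rng(0)
        a = [_outcome(t, True, i) for i, t in enumerate(rng.exponential(10, 20))]
        b = [_outcome(t, True, i) for i, t in enumerate(rng.exponential(14, 20))]
        assert g.logrank_test(a, b) == pytest.approx(g.logrank_test(b, a))

    def test_no_events_rejected(self):
        a = [_outcome(1, False)]
        b = [_outcome(2, False)]
        with pytest.raises(InvalidInputError):
            g.logrank_test(a, b)

    def test_null_rejection_rate_is_alpha(self):
        """Under identical exponential arms the log-rank test rejects at
        close to the nominal 5% level."""
        rng = np.random.default_rng(123)
        n, reps, alpha = 30, 500, 0.05
        rejections = 0
        for _ in range(reps):
            a = [_outcome(t, True, i) for i, t in enumerate(rng.exponential(100, n))]
            b = [_outcome(t, True, i) for i, t in enumerate(rng.exponential(100, n))]
            _, p = g.logrank_test(a, b)
            rejections += p < alpha
        rate = rejections / reps
        band = 2 * np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) <= band + 1e-9


class TestRunTrial:
    def test_deterministic_for_fixed_seed(self):
        spec = g.TrialSpec(n_per_arm=10, seed=5)
        cs = g.CohortSpec()
        r1 = g.run_trial(spec, cs, "C28", "ID14")
        r2 = g.run_trial(spec, cs, "C28", "ID14")
        assert r1.p_value == r2.p_value
        assert r1.gain_months == r2.gain_months
        assert [o.time for o in r1.outcomes_b] == [o.time for o in r2.outcomes_b]

    def test_null_configuration_gain_near_zero(self):
        spec = g.TrialSpec(n_per_arm=40, seed=17)
        r = g.run_trial(spec, g.CohortSpec(), "C28", "C28")
        assert r.p_value > 0.01
        assert abs(r.gain_months) < 18.0  # within between-arm sampling noise

    def test_spaced_doses_beat_cyclic(self):
        r = g.run_trial(g.TrialSpec(n_per_arm=60, seed=2), g.CohortSpec(),
                        "C28", "ID14")
        assert r.median_b > r.median_a


class TestLossOfControl:
    def test_patient3_threshold(self, patient3):
        assert g.loss_of_control_threshold(patient3, 80) == 42

    def test_no_kill_loses_control_at_first_spacing(self):
        # negligible damage and switch rates: the tumor can never shrink
        p = g.ModelParams(rho1=1e-3, rho2=4e-3, psi=1e-10, alpha1=1e-9,
                          alpha2=1e-10, tau=3e-3)
        assert g.loss_of_control_threshold(p, 20) == 7

    def test_strong_kill_never_loses_control(self):
        p = g.ModelParams(rho1=1e-4, rho2=1.5e-4, psi=5.0, alpha1=0.1,
                          alpha2=1e-4, tau=0.05)
        assert g.loss_of_control_threshold(p, 80) is None

    def test_unsorted_spacings_rejected(self, patient3):
        with pytest.raises(InvalidInputError):
            g.loss_of_control_threshold(patient3, 10, spacings=[14, 7])


class TestMaxVolumeLoss:
    def test_monotone_growth_gives_zero(self):
        p = g.ModelParams(rho1=1e-3, rho2=4e-3, psi=1e-10, alpha1=1e-9,
                          alpha2=1e-10, tau=3e-3)
        loss = g.max_volume_loss(p, 10.0, g.build_c28(4))
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_responding_patient_shrinks_under_cyclic(self, patient3):
        assert g.max_volume_loss(patient3, 15.0, g.build_c28(16)) > 0

    def test_tighter_spacing_shrinks_more(self, patient3):
        loss7 = g.max_volume_loss(patient3, 15.0, g.build_id(7, 80))
        loss42 = g.max_volume_loss(patient3, 15.0, g.build_id(42, 80))
        assert loss7 >= loss42


class TestSafetyAndSweep:
    def test_check_safety_weekly_vs_long_spacing(self):
        cohort = g.generate_cohort(g.CohortSpec(n_patients=25, seed=21))
        safe7, offending7 = g.check_safety(cohort, 7)
        assert safe7 and offending7 == []
        safe42, offending42 = g.check_safety(cohort, 42)
        assert safe42 == (len(offending42) == 0)

    def test_sweep_matrix_shape_and_detection(self):
        spec = g.TrialSpec(seed=3)
        p, min_size = g.sample_size_sweep(
            spec, g.CohortSpec(), "ID21", sizes=[10, 30], trials_per_size=3
        )
        assert p.shape == (2, 3)
        assert np.all((p >= 0) & (p <= 1))
        if min_size is not None:
            assert min_size in (10, 30)
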