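"""Tests for mortality machinery: population equations, severity splitting,
month-12 extrapolation, scenarios and the log-normal fit."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from copdcem.engine import run_cohort
from copdcem.mortality import (
    build_schedule,
    fit_lognormal,
    genpop_mortality,
    genpop_survival_update,
    km_conditional_prob,
    proportion_female,
    split_by_severity,
)
from copdcem.parameters import (
    ARM_BGF,
    ARM_FF_UMEC_VI,
    BySeverity,
    ParameterError,
    default_parameters,
)
from copdcem.states import DEATH, N_STATES, STATES
from copdcem.synthetic import SurvivalCurve, add_sampling_noise, make_km_pair


class TestPopulationEquations:
    def test_survival_update_examples(self):
        assert genpop_survival_update(1.0, 0.0) == 1.0
        assert genpop_survival_update(0.5, 1.0) == 0.0
        assert genpop_survival_update(0.9, 0.02) == pytest.approx(0.882)

    def test_proportion_female_equal_survival_preserves_mix(self):
        assert proportion_female(0.8, 0.4, 0.8) == pytest.approx(0.4)

    def test_proportion_female_all_female_start(self):
        assert proportion_female(0.7, 1.0, 0.9) == 1.0

    def test_proportion_female_worked_example(self):
        assert proportion_female(0.8, 0.4, 0.9) == pytest.approx(0.32 / 0.86)
        assert proportion_female(0.8, 0.4, 0.9) == pytest.approx(0.37209, abs=5e-6)

    def test_proportion_female_no_survivors_raises(self):
        with pytest.raises(ParameterError, match="denominator"):
            proportion_female(0.0, 0.5, 0.0)

    def test_weighted_mortality(self):
        assert genpop_mortality(0.01, 0.01, 0.3) == pytest.approx(0.01)
        assert genpop_mortality(0.01, 0.02, 1.0) == pytest.approx(0.01)
        assert genpop_mortality(0.01, 0.02, 0.6) == pytest.approx(0.014)


class TestKmConditionalProb:
    def test_flat_segment_gives_zero(self):
        curve = SurvivalCurve(np.arange(4), np.array([0.0, 0.1, 0.1, 0.1]))
        assert km_conditional_prob(curve, 2) == 0.0

    def test_worked_example(self):
        curve = SurvivalCurve(np.arange(3), np.array([0.0, 0.01, 0.02]))
        assert km_conditional_prob(curve, 2) == pytest.approx(0.01 / 0.99)

    def test_exponential_curve_has_constant_conditional_probability(self):
        h = 0.004
        t = np.arange(25)
        curve = SurvivalCurve(t, 1 - np.exp(-h * t))
        expected = 1 - np.exp(-h)
        for month in range(1, 25):
            assert km_conditional_prob(curve, month) == pytest.approx(
                expected, abs=1e-12
            )

    def test_month_outside_range_raises(self):
        curve = SurvivalCurve(np.arange(3), np.array([0.0, 0.01, 0.02]))
        with pytest.raises(ParameterError, match="range"):
            km_conditional_prob(curve, 5)


class TestSplitBySeverity:
    def test_equal_relative_risks_return_overall(self):
        q = split_by_severity(0.01, (0.2, 0.5, 0.3), (2.0, 2.0, 2.0))
        np.testing.assert_allclose(q, 0.01, atol=1e-15)

    def test_concentrated_occupancy_recovers_overall(self):
        q = split_by_severity(0.03, (0.0, 1.0, 0.0), (1.4, 2.6, 2.6))
        assert q[1] == pytest.approx(0.03, abs=1e-15)

    def test_worked_example_with_published_relative_risks(self):
        q = split_by_severity(0.002, (0.285, 0.606, 0.109), (1.4, 2.6, 2.6))
        b = 0.002 / 2.258
        np.testing.assert_allclose(q, [1.4 * b, 2.6 * b, 2.6 * b], rtol=1e-12)
        np.testing.assert_allclose(q, [1.2400e-3, 2.3029e-3, 2.3029e-3], atol=5e-8)

    @given(
        q=st.floats(min_value=0.0, max_value=0.3),
        occ1=st.floats(min_value=0.05, max_value=0.9),
        rr2=st.floats(min_value=1.0, max_value=5.0),
    )
    def test_weighted_mean_recovers_overall_probability(self, q, occ1, rr2):
        occ = np.array([occ1, (1 - occ1) * 0.7, (1 - occ1) * 0.3])
        rr = np.array([1.0, rr2, rr2 * 1.1])
        qs = split_by_severity(q, occ, rr)
        assert float(occ @ qs) == pytest.approx(q, abs=1e-12)

    def test_impossible_split_raises(self):
        with pytest.raises(ParameterError):
            split_by_severity(1.5, (0.3, 0.4, 0.3), (1.4, 2.6, 2.6))


class TestSchedule:
    def test_identical_inputs_give_identical_schedules(self, ps, inputs):
        same = {
            ARM_BGF: inputs.curves[ARM_FF_UMEC_VI],
            ARM_FF_UMEC_VI: inputs.curves[ARM_FF_UMEC_VI],
        }
        ps.mortality_params.constant_monthly_death = {
            ARM_BGF: 0.002,
            ARM_FF_UMEC_VI: 0.002,
        }
        occ = np.zeros(N_STATES)
        occ[0] = 1.0
        a = build_schedule(ps, ARM_BGF, same, inputs.life_table)
        b = build_schedule(ps, ARM_FF_UMEC_VI, same, inputs.life_table)
        for cycle in (1, 6, 12, 13, 36, 60):
            np.testing.assert_array_equal(
                a.death_probs(cycle, occ), b.death_probs(cycle, occ)
            )

    def test_probabilities_stay_in_unit_interval(self, ps, inputs):
        sched = build_schedule(ps, ARM_BGF, inputs.curves, inputs.life_table)
        trace = run_cohort(ps, ARM_BGF, inputs.curves, inputs.life_table)
        for cycle in range(1, ps.horizon_months + 1):
            q = sched.death_probs(cycle, trace.occupancy[cycle - 1])
            assert np.all(q >= 0) and np.all(q <= 1)

    def test_severe_tunnel_mortality_zero_in_year_one_then_added(self, ps, inputs):
        sched = build_schedule(ps, ARM_BGF, inputs.curves, inputs.life_table)
        occ = np.zeros(N_STATES)
        occ[0] = 1.0
        sev_tunnel = [i for i, s in enumerate(STATES) if s.kind == "tunnel_severe_exac"]
        chronic = [
            i
            for i, s in enumerate(STATES)
            if s.kind == "chronic" and s.history == "none"
        ]
        q6 = sched.death_probs(6, occ)
        np.testing.assert_allclose(q6[sev_tunnel], q6[chronic], atol=1e-15)
        q24 = sched.death_probs(24, occ)
        base = q24[chronic]
        np.testing.assert_allclose(
            q24[sev_tunnel], base + (1 - base) * 0.12, atol=1e-15
        )

    def test_km_mode_reproduces_input_curve_when_rrs_are_one(self, inputs):
        ps = default_parameters()
        ps.horizon_months = 12
        ps.mortality_params.severity_rr = BySeverity(1.0, 1.0, 1.0)
        for arm in (ARM_BGF, ARM_FF_UMEC_VI):
            trace = run_cohort(ps, arm, inputs.curves, inputs.life_table)
            expected = inputs.curves[arm].cumulative_mortality[12]
            assert trace.cumulative_deaths == pytest.approx(expected, abs=1e-9)

    def test_protective_hazard_ratio_orders_cumulative_deaths(self, ps, inputs):
        tr_b = run_cohort(ps, ARM_BGF, inputs.curves, inputs.life_table)
        tr_f = run_cohort(ps, ARM_FF_UMEC_VI, inputs.curves, inputs.life_table)
        deaths_b = tr_b.occupancy[1:, DEATH]
        deaths_f = tr_f.occupancy[1:, DEATH]
        assert np.all(deaths_b < deaths_f)


class TestWaningScenario:
    def test_scalar_is_midpoint_at_month_36(self, ps, inputs):
        sched_b = build_schedule(ps, ARM_BGF, inputs.curves, inputs.life_table, "waning")
        sched_f = build_schedule(
            ps, ARM_FF_UMEC_VI, inputs.curves, inputs.life_table, "waning"
        )
        own = sched_b.calibration_scalar(12)
        other = sched_f.calibration_scalar(36)
        assert sched_b.calibration_scalar(36) == pytest.approx((own + other) / 2)

    def test_death_probs_equal_across_arms_at_month_60(self, ps, inputs):
        sched_b = build_schedule(ps, ARM_BGF, inputs.curves, inputs.life_table, "waning")
        sched_f = build_schedule(
            ps, ARM_FF_UMEC_VI, inputs.curves, inputs.life_table, "waning"
        )
        trace = run_cohort(ps, ARM_BGF, inputs.curves, inputs.life_table, "waning")
        occ = trace.occupancy[59]
        np.testing.assert_array_equal(
            sched_b.death_probs(60, occ), sched_f.death_probs(60, occ)
        )

    def test_waning_shrinks_the_mortality_gap_at_five_years(self, ps, inputs):
        def gap(scenario):
            tb = run_cohort(ps, ARM_BGF, inputs.curves, inputs.life_table, scenario)
            tf = run_cohort(
                ps, ARM_FF_UMEC_VI, inputs.curves, inputs.life_table, scenario
            )
            return tf.cumulative_deaths - tb.cumulative_deaths

        assert 0 < gap("waning") < gap("base")


class TestFitLognormal:
    def test_exact_recovery_on_noise_free_curve(self):
        curves = make_km_pair(
            months=60, shape="lognormal", lognormal_mu=4.0, lognormal_sigma=1.5
        )
        fit = fit_lognormal(curves[ARM_FF_UMEC_VI])
        assert fit.mu == pytest.approx(4.0, abs=1e-6)
        assert fit.sigma == pytest.approx(1.5, abs=1e-6)

    def test_recovery_within_three_standard_errors_on_noisy_curve(self):
        """Binomial noise on a cumulative curve is autocorrelated, so the
        recovery standard error comes from replicate noise realizations."""
        curves = make_km_pair(
            months=60, shape="lognormal", lognormal_mu=4.0, lognormal_sigma=1.5
        )
        curve = curves[ARM_FF_UMEC_VI]
        fits = [
            fit_lognormal(add_sampling_noise(curve, 5000, seed=1000 + k))
            for k in range(30)
        ]
        se_mu = np.std([f.mu for f in fits])
        se_sigma = np.std([f.sigma for f in fits])
        fit = fit_lognormal(add_sampling_noise(curve, 5000, seed=20))
        assert abs(fit.mu - 4.0) < 3 * se_mu
        assert abs(fit.sigma - 1.5) < 3 * se_sigma

    def test_lognormal_fit_beats_exponential_on_lognormal_data(self):
        curves = make_km_pair(
            months=60, shape="lognormal", lognormal_mu=4.0, lognormal_sigma=1.5
        )
        curve = curves[ARM_FF_UMEC_VI]
        fit = fit_lognormal(curve)
        # best single-hazard exponential fit to the same survival points
        t = curve.month[1:].astype(float)
        s = 1 - curve.cumulative_mortality[1:]
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda h: float(((s - np.exp(-h * t)) ** 2).sum()),
            bounds=(1e-6, 1.0),
            method="bounded",
        )
        assert fit.rss <= res.fun

    def test_degenerate_curve_raises(self):
        curve = SurvivalCurve(np.arange(6), np.zeros(6))
        with pytest.raises(ParameterError):
            fit_lognormal(curve)
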