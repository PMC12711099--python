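"""Tests for cost/QALY accumulation and incremental comparison statistics."""

import numpy as np
import pytest

from copdcem.economics import (
    DOMINANT,
    ArmResults,
    CostBreakdown,
    accumulate_costs,
    accumulate_qalys_lys,
    arm_results,
    incremental_outcomes,
)
from copdcem.engine import CohortTrace, run_cohort
from copdcem.model import run_comparison
from copdcem.parameters import (
    ARM_BGF,
    ARM_FF_UMEC_VI,
    BySeverity,
    default_parameters,
)
from copdcem.states import DEATH, N_STATES, chronic_index


def _manual_trace(horizon, occupancy_rows, new_deaths=None, mod=None, sev=None):
    occ = np.array(occupancy_rows, dtype=float)
    return CohortTrace(
        arm=ARM_BGF,
        occupancy=occ,
        new_deaths=np.array(new_deaths or [0.0] * horizon),
        moderate_exacs=np.array(mod or [0.0] * horizon),
        severe_exacs=np.array(sev or [0.0] * horizon),
        frac_on_initial=np.ones(horizon + 1),
        age=np.full(horizon + 1, 65),
    )


def _static_moderate_rows(horizon):
    row = np.zeros(N_STATES)
    row[chronic_index("moderate", "none")] = 1.0
    return [row.copy() for _ in range(horizon + 1)]


def _zero_cost_ps():
    ps = default_parameters()
    ps.discount_rate_costs = 0.0
    ps.discount_rate_outcomes = 0.0
    ps.costs.disease_mgmt_monthly = BySeverity(0.0, 0.0, 0.0)
    ps.costs.moderate_exac_event = 0.0
    ps.costs.severe_exac_event = 0.0
    ps.costs.acquisition_monthly = {ARM_BGF: 0.0, ARM_FF_UMEC_VI: 0.0}
    ps.costs.rescue_monthly = 0.0
    ps.costs.ae_one_time = {ARM_BGF: 0.0, ARM_FF_UMEC_VI: 0.0}
    ps.costs.subsequent_monthly = 0.0
    ps.costs.end_of_life_hospital = 0.0
    return ps


class TestAccumulateCosts:
    def test_zero_cost_parameters_give_zero_components(self):
        ps = _zero_cost_ps()
        trace = _manual_trace(12, _static_moderate_rows(12))
        costs = accumulate_costs(trace, ps, ARM_BGF)
        assert costs.total == 0.0

    def test_severe_exacerbation_event_cost(self):
        # 1% of the cohort has a severe event in cycle 1 at £3667.35/event
        ps = _zero_cost_ps()
        ps.costs.severe_exac_event = 3667.35
        trace = _manual_trace(1, _static_moderate_rows(1), sev=[0.01])
        costs = accumulate_costs(trace, ps, ARM_BGF)
        assert costs.exacerbation_events == pytest.approx(36.6735)
        assert costs.total == pytest.approx(36.6735)

    def test_end_of_life_cost_on_death_entry(self):
        # 10% die in cycle 1; £4028 hospital terminal-care cost each
        ps = _zero_cost_ps()
        ps.costs.end_of_life_hospital = 4028.0
        rows = _static_moderate_rows(1)
        rows[1][chronic_index("moderate", "none")] = 0.9
        rows[1][DEATH] = 0.1
        trace = _manual_trace(1, rows, new_deaths=[0.1])
        costs = accumulate_costs(trace, ps, ARM_BGF)
        assert costs.end_of_life == pytest.approx(402.8)

    def test_adverse_event_cost_applied_once_undiscounted(self):
        ps = _zero_cost_ps()
        ps.discount_rate_costs = 0.10
        ps.costs.ae_one_time = {ARM_BGF: 30.0, ARM_FF_UMEC_VI: 45.0}
        trace = _manual_trace(12, _static_moderate_rows(12))
        assert accumulate_costs(trace, ps, ARM_BGF).adverse_events_one_time == 30.0
        assert accumulate_costs(trace, ps, ARM_FF_UMEC_VI).adverse_events_one_time == 45.0

    def test_treatment_cost_split_follows_on_initial_fraction(self):
        ps = _zero_cost_ps()
        ps.costs.acquisition_monthly = {ARM_BGF: 40.0, ARM_FF_UMEC_VI: 40.0}
        ps.costs.rescue_monthly = 10.0
        ps.costs.subsequent_monthly = 80.0
        trace = _manual_trace(2, _static_moderate_rows(2))
        trace.frac_on_initial = np.array([1.0, 0.5, 0.25])
        costs = accumulate_costs(trace, ps, ARM_BGF)
        assert costs.treatment_initial == pytest.approx(50 * 0.5 + 50 * 0.25)
        assert costs.treatment_subsequent == pytest.approx(80 * 0.5 + 80 * 0.75)


class TestAccumulateQalysLys:
    def test_one_year_static_moderate_cohort_accrues_its_utility(self):
        ps = default_parameters()
        ps.discount_rate_outcomes = 0.0
        trace = _manual_trace(12, _static_moderate_rows(12))
        qalys, lys = accumulate_qalys_lys(trace, ps)
        assert qalys == pytest.approx(0.79, abs=1e-12)
        assert lys == pytest.approx(1.0, abs=1e-12)

    def test_all_dead_cohort_accrues_nothing(self):
        ps = default_parameters()
        rows = [np.zeros(N_STATES) for _ in range(13)]
        for r in rows:
            r[DEATH] = 1.0
        rows[0][DEATH] = 0.0
        rows[0][chronic_index("moderate", "none")] = 1.0
        trace = _manual_trace(12, rows)
        qalys, lys = accumulate_qalys_lys(trace, ps)
        assert qalys == 0.0 and lys == 0.0

    def test_zero_decrement_makes_tunnel_equal_chronic(self):
        ps = default_parameters()
        ps.discount_rate_outcomes = 0.0
        ps.utilities.moderate_exac_decrement = 0.0
        ps.utilities.severe_exac_decrement = 0.0
        from copdcem.states import tunnel_index

        rows = [np.zeros(N_STATES) for _ in range(2)]
        rows[0][chronic_index("severe", "none")] = 1.0
        rows[1][tunnel_index("severe", "moderate_exac")] = 1.0
        trace = _manual_trace(1, rows, mod=[1.0])
        qalys, _ = accumulate_qalys_lys(trace, ps)
        assert qalys == pytest.approx(0.76 / 12)

    def test_tunnel_decrement_reduces_qalys_by_decrement_over_twelve(self):
        ps = default_parameters()
        ps.discount_rate_outcomes = 0.0
        from copdcem.states import tunnel_index

        rows = [np.zeros(N_STATES) for _ in range(2)]
        rows[0][chronic_index("severe", "none")] = 1.0
        rows[1][tunnel_index("severe", "severe_exac")] = 1.0
        trace = _manual_trace(1, rows, sev=[1.0])
        qalys, _ = accumulate_qalys_lys(trace, ps)
        assert qalys == pytest.approx((0.76 - 0.090) / 12)

    def test_lump_sum_decrement_switch(self):
        ps = default_parameters()
        ps.discount_rate_outcomes = 0.0
        ps.lump_sum_decrements = True
        from copdcem.states import tunnel_index

        rows = [np.zeros(N_STATES) for _ in range(3)]
        rows[0][chronic_index("severe", "none")] = 1.0
        rows[1][chronic_index("severe", "none")] = 1.0
        rows[2][tunnel_index("severe", "severe_exac")] = 1.0
        trace = _manual_trace(2, rows, sev=[0.0, 1.0])
        qalys, _ = accumulate_qalys_lys(trace, ps)
        assert qalys == pytest.approx(2 * 0.76 / 12 - 0.090)


class TestDiscountingProperties:
    def test_zero_rates_equal_undiscounted_sums(self, ps, inputs):
        ps.discount_rate_costs = 0.0
        ps.discount_rate_outcomes = 0.0
        trace = run_cohort(ps, ARM_BGF, inputs.curves, inputs.life_table)
        res = arm_results(trace, ps, ARM_BGF)
        # independent undiscounted recomputation
        alive = 1.0 - trace.occupancy[1:, DEATH]
        assert res.lys == pytest.approx(alive.sum() / 12, abs=1e-9)
        assert res.lys == pytest.approx(res.lys_undiscounted, abs=1e-12)
        eol = trace.new_deaths.sum() * ps.costs.end_of_life_hospital
        assert res.costs.end_of_life == pytest.approx(eol, abs=1e-9)

    def test_positive_rates_strictly_reduce_totals(self, inputs):
        ps0 = default_parameters()
        ps0.discount_rate_costs = 0.0
        ps0.discount_rate_outcomes = 0.0
        ps1 = default_parameters()
        t0 = run_cohort(ps0, ARM_BGF, inputs.curves, inputs.life_table)
        r0 = arm_results(t0, ps0, ARM_BGF)
        r1 = arm_results(t0, ps1, ARM_BGF)
        assert r1.qalys < r0.qalys
        assert r1.lys < r0.lys
        for key, value in r1.costs.as_dict().items():
            if key == "adverse_events_one_time":  # booked at model start
                continue
            assert value < r0.costs.as_dict()[key]


def _arm(total_cost, qalys, lys=1.0, exacs=0.0, deaths=0.0, arm=ARM_BGF):
    return ArmResults(
        arm=arm,
        costs=CostBreakdown(disease_management=total_cost),
        qalys=qalys,
        lys=lys,
        lys_undiscounted=lys,
        total_exacerbations=exacs,
        cumulative_deaths=deaths,
    )


class TestIncrementalOutcomes:
    def test_identical_arms_all_increments_zero(self):
        a = _arm(100.0, 2.0)
        b = _arm(100.0, 2.0, arm=ARM_FF_UMEC_VI)
        inc = incremental_outcomes(a, b, 20000)
        assert inc.delta_cost == 0.0
        assert inc.delta_qalys == 0.0
        assert inc.icur_per_qaly is None  # undefined, not a number
        assert inc.inb_at_threshold == 0.0

    def test_net_benefit_arithmetic_on_published_increments(self):
        # dQ = 0.21, dC = -23.03 at £20,000/QALY
        a = _arm(976.97, 3.11, deaths=0.12)
        b = _arm(1000.0, 2.90, deaths=0.28, arm=ARM_FF_UMEC_VI)
        inc = incremental_outcomes(a, b, 20000)
        assert inc.inb_at_threshold == pytest.approx(4223.03)
        assert inc.deaths_avoided_pct == pytest.approx(16.0)

    def test_dominance_flag_replaces_ratios(self):
        a = _arm(90.0, 2.5, lys=3.0)
        b = _arm(100.0, 2.0, lys=2.5, arm=ARM_FF_UMEC_VI)
        inc = incremental_outcomes(a, b, 20000)
        assert inc.dominance_flag == DOMINANT
        assert inc.icur_per_qaly == "dominant"
        assert inc.icer_per_ly == "dominant"

    def test_nondominant_ratios_are_quotients(self):
        a = _arm(150.0, 2.5, lys=3.0)
        b = _arm(100.0, 2.0, lys=2.5, arm=ARM_FF_UMEC_VI)
        inc = incremental_outcomes(a, b, 20000)
        assert inc.icur_per_qaly == pytest.approx(100.0)
        assert inc.icer_per_ly == pytest.approx(100.0)
        assert inc.dominance_flag is None


class TestMortalityCostMechanism:
    def test_survival_gain_raises_treatment_and_lowers_eol_costs(self, ps, inputs):
        """Lower mortality (HR < 1) must buy life years at the price of higher
        treatment spend, recouped in end-of-life spend."""
        res = run_comparison(ps, inputs)
        inc = res.incremental
        assert inc.delta_lys > 0
        assert inc.delta_cost_by_category["treatment_initial"] > 0
        assert inc.delta_cost_by_category["treatment_subsequent"] > 0
        assert inc.delta_cost_by_category["end_of_life"] < 0
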