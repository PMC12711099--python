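"""Two-arm orchestration: run both treatment arms and compare them.

This is the surface the sensitivity analyses, the command line and the
reproduction script all drive. ``default_model_inputs`` builds the synthetic
external inputs (curve pair at the published hazard ratio, life table) sized
to the parameter set's horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .economics import ArmResults, IncrementalResults, arm_results, incremental_outcomes
from .engine import CohortTrace, run_cohort
from .parameters import ARM_BGF, ARM_FF_UMEC_VI, ParameterSet
from .synthetic import (
    DEFAULT_HAZARD_RATIO,
    DEFAULT_REF_MONTHLY_HAZARD,
    LifeTable,
    SurvivalCurve,
    make_km_pair,
    make_life_table,
)


@dataclass
class ModelInputs:
    """External inputs shared by both arms."""

    curves: dict[str, SurvivalCurve]
    life_table: LifeTable


def default_model_inputs(
    ps: ParameterSet,
    hazard_ratio: float = DEFAULT_HAZARD_RATIO,
    ref_monthly_hazard: float = DEFAULT_REF_MONTHLY_HAZARD,
) -> ModelInputs:
    months = max(12, ps.horizon_months)
    curves = make_km_pair(
        ref_monthly_hazard=ref_monthly_hazard,
        hazard_ratio=hazard_ratio,
        months=months,
    )
    horizon_years = (ps.horizon_months - 1) // 12 + 1
    life_table = make_life_table(
        baseline_age=ps.baseline_age,
        max_age=ps.baseline_age + horizon_years + 1,
    )
    return ModelInputs(curves=curves, life_table=life_table)


@dataclass
class ComparisonResults:
    bgf: ArmResults
    ffumecvi: ArmResults
    incremental: IncrementalResults
    traces: dict[str, CohortTrace]

    def summary_frame(self) -> pd.DataFrame:
        """Human-readable outcome rows mirroring the dominance-analysis table."""
        inc = self.incremental

        def fmt(v):
            return v if v is not None else "undefined"

        rows = [
            ("ICUR (cost per QALY gained)", fmt(inc.icur_per_qaly)),
            ("ICER (cost per LY gained)", fmt(inc.icer_per_ly)),
            ("Incremental costs per mortality avoided", fmt(inc.cost_per_death_avoided)),
            (
                f"Incremental net benefits at willingness-to-pay of {inc.threshold:.0f}",
                inc.inb_at_threshold,
            ),
            ("Total incremental costs", inc.delta_cost),
            (
                "Incremental disease management costs",
                inc.delta_cost_by_category["disease_management"]
                + inc.delta_cost_by_category["exacerbation_events"],
            ),
            (
                "Incremental treatment-specific costs",
                inc.delta_cost_by_category["treatment_initial"]
                + inc.delta_cost_by_category["adverse_events_one_time"],
            ),
            (
                "Incremental subsequent treatment costs",
                inc.delta_cost_by_category["treatment_subsequent"],
            ),
            (
                "Incremental end-of-life costs",
                inc.delta_cost_by_category["end_of_life"],
            ),
            ("Total incremental QALYs", inc.delta_qalys),
            ("Total incremental LYs", inc.delta_lys),
            ("Total incremental exacerbations", inc.delta_exacerbations),
            ("Total incremental deaths avoided (%)", inc.deaths_avoided_pct),
        ]
        return pd.DataFrame(rows, columns=["outcome", "BGF vs FF/UMEC/VI"])

    def per_arm_frame(self) -> pd.DataFrame:
        """Per-arm totals mirroring the cost/outcome table."""
        rows = []
        for res in (self.bgf, self.ffumecvi):
            d = res.costs.as_dict()
            rows.append(
                {
                    "arm": res.arm,
                    "total_costs": d["total"],
                    "disease_management_costs": d["disease_management"]
                    + d["exacerbation_events"],
                    "treatment_costs_before_discontinuation": d["treatment_initial"]
                    + d["adverse_events_one_time"],
                    "subsequent_treatment_costs": d["treatment_subsequent"],
                    "end_of_life_costs": d["end_of_life"],
                    "total_qalys": res.qalys,
                    "total_lys": res.lys,
                    "total_lys_undiscounted": res.lys_undiscounted,
                    "total_exacerbations": res.total_exacerbations,
                    "cumulative_deaths": res.cumulative_deaths,
                }
            )
        return pd.DataFrame(rows)


def run_comparison(
    ps: ParameterSet,
    inputs: ModelInputs | None = None,
    scenario: str = "base",
    keep_matrices: bool = False,
) -> ComparisonResults:
    """Run both arms under a scenario and compute all comparison statistics.

    The ``eol_setting`` scenario swaps the base-case (all-hospital)
    end-of-life cost for the care-setting-mix weighted cost; the mortality
    scenarios are dispatched into the arm schedules.
    """
    if inputs is None:
        inputs = default_model_inputs(ps)

    run_ps = ps
    mortality_scenario = scenario
    if scenario == "eol_setting":
        run_ps = ps.copy()
        run_ps.costs.end_of_life_hospital = ps.costs.end_of_life_setting_weighted()
        mortality_scenario = "base"

    arms: dict[str, ArmResults] = {}
    traces: dict[str, CohortTrace] = {}
    for arm in (ARM_BGF, ARM_FF_UMEC_VI):
        trace = run_cohort(
            run_ps,
            arm,
            inputs.curves,
            inputs.life_table,
            scenario=mortality_scenario,
            keep_matrices=keep_matrices,
        )
        traces[arm] = trace
        arms[arm] = arm_results(trace, run_ps, arm)

    inc = incremental_outcomes(
        arms[ARM_BGF], arms[ARM_FF_UMEC_VI], threshold=run_ps.wtp_threshold
    )
    return ComparisonResults(
        bgf=arms[ARM_BGF],
        ffumecvi=arms[ARM_FF_UMEC_VI],
        incremental=inc,
        traces=traces,
    )
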