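"""Discounted costs, QALYs, life years and incremental comparison statistics.

Accounting conventions: state-time accruals (disease management, treatment,
utilities, life years) are booked against end-of-cycle occupancy (optionally
the half-cycle average); exacerbation event costs in the tunnel-entry cycle;
the end-of-life cost in the death cycle; adverse-event costs once at model
start, undiscounted. Exacerbation utility decrements are applied as reduced
utility during the one-cycle tunnel residence (QALY loss = decrement/12 per
event) unless the lump-sum switch is on, in which case the full decrement is
subtracted per event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .engine import CohortTrace
from .parameters import ParameterSet, discount_factor
from .states import DEATH, STATES

logger = logging.getLogger(__name__)

DOMINANT = "less costly and more effective"
DOMINATED = "more costly and less effective"


@dataclass
class CostBreakdown:
    """Discounted cost totals by category (GBP)."""

    disease_management: float = 0.0
    treatment_initial: float = 0.0
    treatment_subsequent: float = 0.0
    exacerbation_events: float = 0.0
    adverse_events_one_time: float = 0.0
    end_of_life: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.disease_management
            + self.treatment_initial
            + self.treatment_subsequent
            + self.exacerbation_events
            + self.adverse_events_one_time
            + self.end_of_life
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "disease_management": self.disease_management,
            "treatment_initial": self.treatment_initial,
            "treatment_subsequent": self.treatment_subsequent,
            "exacerbation_events": self.exacerbation_events,
            "adverse_events_one_time": self.adverse_events_one_time,
            "end_of_life": self.end_of_life,
            "total": self.total,
        }


@dataclass
class ArmResults:
    """Everything accumulated from one arm's trace."""

    arm: str
    costs: CostBreakdown
    qalys: float
    lys: float
    lys_undiscounted: float
    total_exacerbations: float
    cumulative_deaths: float


@dataclass
class IncrementalResults:
    """Intervention-minus-comparator statistics (BGF minus FF/UMEC/VI)."""

    delta_cost: float
    delta_cost_by_category: dict[str, float]
    delta_qalys: float
    delta_lys: float
    delta_exacerbations: float
    deaths_avoided_pct: float  # 100 * (comparator deaths - intervention deaths)
    inb_at_threshold: float
    threshold: float
    icur_per_qaly: float | str | None
    icer_per_ly: float | str | None
    cost_per_death_avoided: float | str | None
    dominance_flag: str | None


def _state_time(trace: CohortTrace, half_cycle: bool) -> np.ndarray:
    """State time attributed to each cycle: (horizon, 16)."""
    occ = trace.occupancy
    if half_cycle:
        return 0.5 * (occ[:-1] + occ[1:])
    return occ[1:]


def accumulate_costs(trace: CohortTrace, ps: ParameterSet, arm: str) -> CostBreakdown:
    """Discounted cost totals by category for one arm."""
    cs = ps.costs
    horizon = trace.horizon
    delta = np.array(
        [discount_factor(ps.discount_rate_costs, t) for t in range(1, horizon + 1)]
    )
    occ_t = _state_time(trace, ps.half_cycle_correction)

    mgmt_by_state = np.array(
        [
            cs.disease_mgmt_monthly[st.severity] if st.kind != "death" else 0.0
            for st in STATES
        ]
    )
    out = CostBreakdown()
    out.disease_management = float(((occ_t @ mgmt_by_state) * delta).sum())

    alive = 1.0 - occ_t[:, DEATH]
    frac_init = trace.frac_on_initial[1:]
    acq = cs.acquisition_monthly[arm] + cs.rescue_monthly
    out.treatment_initial = float((alive * frac_init * acq * delta).sum())
    out.treatment_subsequent = float(
        (alive * (1.0 - frac_init) * cs.subsequent_monthly * delta).sum()
    )

    out.exacerbation_events = float(
        (
            (
                trace.moderate_exacs * cs.moderate_exac_event
                + trace.severe_exacs * cs.severe_exac_event
            )
            * delta
        ).sum()
    )

    eol_cost = cs.end_of_life_hospital
    out.end_of_life = float((trace.new_deaths * eol_cost * delta).sum())

    out.adverse_events_one_time = float(cs.ae_one_time[arm])  # model start, undiscounted
    return out


def accumulate_qalys_lys(trace: CohortTrace, ps: ParameterSet) -> tuple[float, float]:
    """Discounted (QALYs, LYs) for one arm; see module docstring for the
    decrement conventions."""
    ut = ps.utilities
    horizon = trace.horizon
    delta = np.array(
        [discount_factor(ps.discount_rate_outcomes, t) for t in range(1, horizon + 1)]
    )
    occ_t = _state_time(trace, ps.half_cycle_correction)

    utility_by_state = np.zeros(len(STATES))
    for i, st in enumerate(STATES):
        if st.kind == "death":
            utility_by_state[i] = ut.death_utility
        elif st.kind == "chronic":
            utility_by_state[i] = ut.severity_utility[st.severity]
        else:
            u = ut.severity_utility[st.severity]
            if not ps.lump_sum_decrements:
                dec = (
                    ut.moderate_exac_decrement
                    if st.kind == "tunnel_moderate_exac"
                    else ut.severe_exac_decrement
                )
                u = u - dec
                if u < 0:
                    logger.warning(
                        "utility for %s negative after decrement; clamped to 0",
                        st.label(),
                    )
                    u = 0.0
            utility_by_state[i] = u

    qalys = float(((occ_t @ utility_by_state) / 12.0 * delta).sum())
    if ps.lump_sum_decrements:
        qalys -= float(
            (
                (
                    trace.moderate_exacs * ut.moderate_exac_decrement
                    + trace.severe_exacs * ut.severe_exac_decrement
                )
                * delta
            ).sum()
        )
        qalys = max(qalys, 0.0)

    alive = 1.0 - occ_t[:, DEATH]
    lys = float((alive / 12.0 * delta).sum())
    return qalys, lys


def undiscounted_lys(trace: CohortTrace, ps: ParameterSet) -> float:
    occ_t = _state_time(trace, ps.half_cycle_correction)
    return float(((1.0 - occ_t[:, DEATH]) / 12.0).sum())


def arm_results(trace: CohortTrace, ps: ParameterSet, arm: str) -> ArmResults:
    costs = accumulate_costs(trace, ps, arm)
    qalys, lys = accumulate_qalys_lys(trace, ps)
    return ArmResults(
        arm=arm,
        costs=costs,
        qalys=qalys,
        lys=lys,
        lys_undiscounted=undiscounted_lys(trace, ps),
        total_exacerbations=float(
            trace.moderate_exacs.sum() + trace.severe_exacs.sum()
        ),
        cumulative_deaths=trace.cumulative_deaths,
    )


def incremental_outcomes(
    a: ArmResults, b: ArmResults, threshold: float
) -> IncrementalResults:
    """Comparison statistics for intervention ``a`` versus comparator ``b``."""
    dc = a.costs.total - b.costs.total
    dq = a.qalys - b.qalys
    dly = a.lys - b.lys
    deaths_avoided = b.cumulative_deaths - a.cumulative_deaths

    dominance = None
    if dc < 0 and dq > 0:
        dominance = DOMINANT
    elif dc > 0 and dq < 0:
        dominance = DOMINATED

    def ratio(num: float, den: float) -> float | str | None:
        if dominance == DOMINANT:
            return "dominant"
        if dominance == DOMINATED:
            return "dominated"
        if den == 0:
            return None  # undefined
        return num / den

    by_cat = {
        k: a.costs.as_dict()[k] - b.costs.as_dict()[k]
        for k in a.costs.as_dict()
        if k != "total"
    }
    return IncrementalResults(
        delta_cost=dc,
        delta_cost_by_category=by_cat,
        delta_qalys=dq,
        delta_lys=dly,
        delta_exacerbations=a.total_exacerbations - b.total_exacerbations,
        deaths_avoided_pct=100.0 * deaths_avoided,
        inb_at_threshold=threshold * dq - dc,
        threshold=threshold,
        icur_per_qaly=ratio(dc, dq),
        icer_per_ly=ratio(dc, dly),
        cost_per_death_avoided=ratio(dc, deaths_avoided),
        dominance_flag=dominance,
    )
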