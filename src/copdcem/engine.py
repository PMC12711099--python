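"""Monthly cohort simulation for one treatment arm.

Iterates the occupancy vector through the per-cycle transition matrices over
the model horizon, recording new deaths, exacerbation tunnel entries and the
split between initial and subsequent treatment. Treatment status is tracked
as a scalar fraction among the alive rather than by doubling the state
space: subsequent treatment has the same efficacy as initial treatment, so
only the cost attribution differs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mortality import MortalitySchedule, build_schedule
from .parameters import ParameterError, ParameterSet
from .states import (
    DEATH,
    N_STATES,
    STATE_LABELS,
    TUNNEL_MOD_MASK,
    TUNNEL_SEV_MASK,
    build_transition_matrix,
    initial_cohort,
)
from .synthetic import LifeTable, SurvivalCurve

_CONSERVATION_TOL = 1e-9


@dataclass
class CohortTrace:
    """Cycle-by-cycle record of one arm's cohort run.

    ``occupancy[t]`` is the distribution after cycle ``t`` (row 0 = start);
    event arrays are indexed by cycle 1..horizon (entry ``t-1``).
    """

    arm: str
    occupancy: np.ndarray  # (horizon+1, 16)
    new_deaths: np.ndarray  # (horizon,)
    moderate_exacs: np.ndarray  # (horizon,)
    severe_exacs: np.ndarray  # (horizon,)
    frac_on_initial: np.ndarray  # (horizon+1,) among the alive
    age: np.ndarray  # (horizon+1,) cohort age in whole years
    matrices: list[np.ndarray] | None = None

    @property
    def horizon(self) -> int:
        return self.new_deaths.shape[0]

    @property
    def alive(self) -> np.ndarray:
        """Fraction alive after each cycle (index 0 = start)."""
        return 1.0 - self.occupancy[:, DEATH]

    @property
    def cumulative_deaths(self) -> float:
        return float(self.occupancy[-1, DEATH])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=STATE_LABELS)
        df.insert(0, "cycle", np.arange(self.horizon + 1))
        df["new_deaths"] = np.concatenate([[0.0], self.new_deaths])
        df["moderate_exacs"] = np.concatenate([[0.0], self.moderate_exacs])
        df["severe_exacs"] = np.concatenate([[0.0], self.severe_exacs])
        df["frac_on_initial"] = self.frac_on_initial
        df["age"] = self.age
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class EventSummary:
    total_moderate_exacs: float
    total_severe_exacs: float
    cumulative_deaths: float
    new_deaths: np.ndarray

    @property
    def total_exacs(self) -> float:
        return self.total_moderate_exacs + self.total_severe_exacs


def update_treatment_status(frac_on_initial: float, cycle: int, ps: ParameterSet,
                            arm: str) -> float:
    """Apply one cycle of treatment discontinuation to the on-initial fraction.

    First-year cycles use the arm's trial-based monthly discontinuation risk;
    from cycle 13 a flat 1% per cycle applies. Discontinued patients move to
    subsequent treatment and stay there until death.
    """
    if not 0.0 <= frac_on_initial <= 1.0:
        raise ParameterError(f"frac_on_initial={frac_on_initial!r} not in [0, 1]")
    return frac_on_initial * (1.0 - ps.discontinuation.monthly(arm, cycle))


def run_cohort(
    ps: ParameterSet,
    arm: str,
    curves: dict[str, SurvivalCurve],
    life_table: LifeTable,
    scenario: str = "base",
    schedule: MortalitySchedule | None = None,
    keep_matrices: bool = False,
) -> CohortTrace:
    """Run the deterministic cohort simulation over ``ps.horizon_months``."""
    horizon = ps.horizon_months
    if schedule is None:
        schedule = build_schedule(ps, arm, curves, life_table, scenario)

    occupancy = np.zeros((horizon + 1, N_STATES))
    occupancy[0] = initial_cohort(ps)
    new_deaths = np.zeros(horizon)
    mod_exacs = np.zeros(horizon)
    sev_exacs = np.zeros(horizon)
    frac_init = np.ones(horizon + 1)
    age = np.zeros(horizon + 1, dtype=int)
    age[0] = ps.baseline_age
    matrices: list[np.ndarray] = []

    occ = occupancy[0]
    for t in range(1, horizon + 1):
        q = schedule.death_probs(t, occ)
        tm = build_transition_matrix(ps, arm, t, q)
        nxt = occ @ tm.entries
        if abs(nxt.sum() - 1.0) > _CONSERVATION_TOL:
            raise ParameterError(
                f"mass conservation broken at cycle {t}: total={nxt.sum()!r}"
            )
        new_deaths[t - 1] = nxt[DEATH] - occ[DEATH]
        mod_exacs[t - 1] = float(occ @ tm.entries[:, TUNNEL_MOD_MASK].sum(axis=1))
        sev_exacs[t - 1] = float(occ @ tm.entries[:, TUNNEL_SEV_MASK].sum(axis=1))
        frac_init[t] = update_treatment_status(frac_init[t - 1], t, ps, arm)
        age[t] = ps.baseline_age + (t - 1) // 12
        occupancy[t] = nxt
        if keep_matrices:
            matrices.append(tm.entries)
        occ = nxt

    return CohortTrace(
        arm=arm,
        occupancy=occupancy,
        new_deaths=new_deaths,
        moderate_exacs=mod_exacs,
        severe_exacs=sev_exacs,
        frac_on_initial=frac_init,
        age=age,
        matrices=matrices if keep_matrices else None,
    )


def count_events(trace: CohortTrace) -> EventSummary:
    """Totals of exacerbation tunnel entries and deaths over the horizon."""
    return EventSummary(
        total_moderate_exacs=float(trace.moderate_exacs.sum()),
        total_severe_exacs=float(trace.severe_exacs.sum()),
        cumulative_deaths=trace.cumulative_deaths,
        new_deaths=trace.new_deaths.copy(),
    )
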