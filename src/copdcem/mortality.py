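"""Per-cycle, per-state death probabilities for each treatment arm.

Year 1 takes the overall monthly death probability from the arm's
cumulative-mortality curve (KM mode) or from a constant monthly input, and
splits it across severity levels each cycle with published relative risks,
weighted by where the cohort currently sits. Beyond month 12 the model
switches to age-advancing general-population mortality multiplied by the
severity relative risk and an arm-level calibration scalar — the ratio of the
arm's instantaneous hazard at month 12 to the severity-weighted
general-population hazard at the same point, clamped to at least 1 so modelled
patients are never healthier than the matched general population. Severe
exacerbation tunnel states additionally carry a one-cycle 12% event mortality
beyond year 1 (0% within year 1, where trial mortality already counts those
deaths).

Two scenario hooks modify the extrapolation: ``waning`` interpolates the BGF
scalar linearly toward the comparator's between months 12 and 60, and
``lognormal`` replaces the post-month-12 overall hazard with conditional
probabilities from a log-normal fit to the arm's curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import norm

from .parameters import (
    ARM_BGF,
    ARM_FF_UMEC_VI,
    SEVERITIES,
    ParameterError,
    ParameterSet,
)
from .states import DEATH, N_STATES, SEVERITY_OF, STATES
from .synthetic import LifeTable, SurvivalCurve

SCENARIOS = ("base", "waning", "lognormal", "eol_setting")

WANING_START_MONTH = 12
WANING_END_MONTH = 60


# ---------------------------------------------------------------------------
# General-population machinery
# ---------------------------------------------------------------------------


def genpop_survival_update(prop_alive_prev: float, qx_prev: float) -> float:
    """Advance the proportion alive one year: ``(1 - qx) * S``."""
    return (1.0 - qx_prev) * prop_alive_prev


def proportion_female(p1: float, p2: float, p3: float) -> float:
    """Proportion female among survivors at age x.

    ``p1``/``p3`` are the fractions of the starting females/males still
    alive; ``p2`` is the proportion female at model start.
    """
    denom = p1 * p2 + (1.0 - p2) * p3
    if denom <= 0:
        raise ParameterError("no survivors of either sex: zero denominator")
    return p1 * p2 / denom


def genpop_mortality(r1: float, r2: float, p: float) -> float:
    """Sex-weighted general-population mortality: ``r1*p + r2*(1-p)``."""
    return r1 * p + r2 * (1.0 - p)


def km_conditional_prob(curve: SurvivalCurve, month: int) -> float:
    """Per-cycle conditional death probability from a cumulative curve:
    ``(M(t) - M(t-1)) / (1 - M(t-1))``."""
    if month < 1 or month > curve.max_month:
        raise ParameterError(f"month {month} outside curve range 1..{curve.max_month}")
    m = curve.cumulative_mortality
    surv_prev = 1.0 - m[month - 1]
    if surv_prev <= 0:
        raise ParameterError(f"no survivors at month {month - 1}")
    return float((m[month] - m[month - 1]) / surv_prev)


def split_by_severity(
    q_overall: float,
    occupancy: tuple[float, float, float] | np.ndarray,
    rr: tuple[float, float, float] | np.ndarray,
) -> np.ndarray:
    """Split an overall death probability across severity levels.

    Solves ``q_s = b * rr_s`` with ``b = q / sum(occ_s * rr_s)`` so the
    occupancy-weighted mean of the per-severity probabilities recovers the
    overall probability; entries are capped at 1 with the remainder
    re-normalized over uncapped severities.
    """
    occ = np.asarray(occupancy, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if q_overall > 1.0 or q_overall < 0.0:
        raise ParameterError(f"q_overall={q_overall!r} must be in [0, 1]")
    if np.any(rr <= 0):
        raise ParameterError("relative risks must be > 0")

    q = np.zeros_like(rr)
    uncapped = np.ones_like(rr, dtype=bool)
    remaining = q_overall
    for _ in range(len(rr)):
        w = float(occ[uncapped] @ rr[uncapped])
        if w <= 0:
            if remaining > 1e-15:
                raise ParameterError(
                    "severity split impossible: capped probabilities cannot "
                    f"absorb q_overall={q_overall}"
                )
            b = 0.0
        else:
            b = remaining / w
        cand = b * rr
        over = uncapped & (cand > 1.0)
        if not over.any():
            q[uncapped] = cand[uncapped]
            return q
        q[over] = 1.0
        remaining -= float(occ[over].sum())
        uncapped &= ~over
        if remaining < 0:
            raise ParameterError("severity split impossible after capping")
    if remaining > 1e-12:
        raise ParameterError("severity split impossible: all severities capped")
    return q


# ---------------------------------------------------------------------------
# Log-normal fit
# ---------------------------------------------------------------------------


@dataclass
class LognormalFit:
    mu: float
    sigma: float
    rss: float
    se_mu: float
    se_sigma: float

    def survival(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = np.ones_like(t)
        pos = t > 0
        out[pos] = norm.sf((np.log(t[pos]) - self.mu) / self.sigma)
        return out


def fit_lognormal(curve: SurvivalCurve) -> LognormalFit:
    """Least-squares log-normal fit to the monthly survival points.

    Fits ``S(t) = 1 - Phi((ln t - mu)/sigma)`` over months ``t >= 1``;
    initialized by probit regression of the cumulative mortality on ``ln t``.
    """
    t = curve.month[1:].astype(float)
    m = curve.cumulative_mortality[1:]
    if np.count_nonzero(np.diff(curve.cumulative_mortality) > 0) < 3:
        raise ParameterError("curve needs at least 3 strictly increasing values")
    if m[-1] <= 0:
        raise ParameterError("degenerate curve: no deaths")

    inside = (m > 0) & (m < 1)
    z = norm.ppf(m[inside])
    slope, intercept = np.polyfit(np.log(t[inside]), z, 1)
    sigma0 = 1.0 / slope if slope > 0 else 1.0
    mu0 = -intercept * sigma0

    def model(tt, mu, sigma):
        return norm.sf((np.log(tt) - mu) / sigma)

    popt, pcov = curve_fit(
        model,
        t,
        1.0 - m,
        p0=(mu0, max(sigma0, 1e-3)),
        bounds=([-np.inf, 1e-6], [np.inf, np.inf]),
        maxfev=10000,
    )
    resid = (1.0 - m) - model(t, *popt)
    ses = np.sqrt(np.diag(pcov))
    return LognormalFit(
        mu=float(popt[0]),
        sigma=float(popt[1]),
        rss=float(resid @ resid),
        se_mu=float(ses[0]),
        se_sigma=float(ses[1]),
    )


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------


def _monthly_from_annual(rate: float) -> float:
    return 1.0 - (1.0 - rate) ** (1.0 / 12.0)


class MortalitySchedule:
    """Arm-level death-probability generator, queried cycle by cycle.

    The severity split within year 1 depends on where the cohort currently
    sits, so the cohort engine passes the live occupancy vector into
    :meth:`death_probs` each cycle; everything else (year-1 overall
    probabilities, the general-population track, the calibration scalars) is
    precomputed at construction.
    """

    def __init__(
        self,
        ps: ParameterSet,
        arm: str,
        curves: dict[str, SurvivalCurve],
        life_table: LifeTable,
        scenario: str = "base",
    ) -> None:
        if scenario not in SCENARIOS:
            raise ParameterError(
                f"unknown scenario {scenario!r}; valid: {', '.join(SCENARIOS)}"
            )
        self.ps = ps
        self.arm = arm
        self.mode = ps.mortality_mode
        self.scenario = scenario
        horizon = ps.horizon_months

        # overall monthly death probability, cycles 1..12
        self._q_year1 = {}
        for a in (ARM_BGF, ARM_FF_UMEC_VI):
            if self.mode == "km_curve":
                curve = curves[a]
                if curve.max_month < min(12, horizon):
                    raise ParameterError(
                        f"curve for {a} covers {curve.max_month} months; "
                        f"needs at least {min(12, horizon)}"
                    )
                self._q_year1[a] = np.array(
                    [
                        km_conditional_prob(curve, t)
                        for t in range(1, min(12, horizon) + 1)
                    ]
                )
            else:
                q = ps.mortality_params.constant_monthly_death[a]
                self._q_year1[a] = np.full(min(12, horizon), q)

        # general-population monthly probability per cycle (age-advancing)
        self._genpop_monthly = self._build_genpop_track(ps, life_table, horizon)

        # month-12 extrapolation anchors (both arms, for the waning scenario)
        self._scalar = {}
        if horizon > 12:
            rr = np.array(ps.mortality_params.severity_rr.as_tuple())
            w0 = np.array(ps.baseline_distribution.as_tuple())
            q_gp12 = self._genpop_monthly[11]  # cycle 12
            h_gp = -math.log(1.0 - float(w0 @ rr) * q_gp12)
            if h_gp <= 0:
                raise ParameterError("general-population hazard is 0 at the anchor")
            for a in (ARM_BGF, ARM_FF_UMEC_VI):
                q12 = self._q_year1[a][11]
                h_arm = -math.log(1.0 - q12)
                self._scalar[a] = max(1.0, h_arm / h_gp)

        self._lognormal_fit = None
        if scenario == "lognormal":
            self._lognormal_fit = fit_lognormal(curves[arm])

    @staticmethod
    def _build_genpop_track(
        ps: ParameterSet, life_table: LifeTable, horizon: int
    ) -> np.ndarray:
        """Monthly general-population death probability for cycles 1..horizon,
        with age advanced in whole years and the sex mix updated from the
        life table's survival."""
        n_years = (horizon - 1) // 12 + 1
        s_f = s_m = 1.0
        track = np.empty(horizon)
        for y in range(n_years):
            age = ps.baseline_age + y
            p_fem = proportion_female(s_f, ps.proportion_female, s_m)
            annual = genpop_mortality(
                life_table.qx(age, "female"), life_table.qx(age, "male"), p_fem
            )
            q_m = _monthly_from_annual(annual)
            track[y * 12 : min((y + 1) * 12, horizon)] = q_m
            s_f = genpop_survival_update(s_f, life_table.qx(age, "female"))
            s_m = genpop_survival_update(s_m, life_table.qx(age, "male"))
        return track

    # -- scalar with scenario hooks ----------------------------------------

    def calibration_scalar(self, cycle: int) -> float:
        own = self._scalar[self.arm]
        if self.scenario != "waning" or self.arm != ARM_BGF:
            return own
        other = self._scalar[ARM_FF_UMEC_VI]
        w = (cycle - WANING_START_MONTH) / (WANING_END_MONTH - WANING_START_MONTH)
        w = min(max(w, 0.0), 1.0)
        return (1.0 - w) * own + w * other

    # -- per-cycle probabilities -------------------------------------------

    def _severity_mix(self, occupancy: np.ndarray) -> np.ndarray:
        mix = np.zeros(3)
        for i, st in enumerate(STATES):
            if i == DEATH:
                continue
            mix[SEVERITIES.index(SEVERITY_OF[i])] += occupancy[i]
        total = mix.sum()
        if total <= 0:
            return np.array(self.ps.baseline_distribution.as_tuple())
        return mix / total

    def overall_prob(self, cycle: int) -> float | None:
        """The overall (pre-split) probability where one exists: year-1
        cycles and log-normal-extrapolated cycles; ``None`` where the
        per-severity general-population composition applies directly."""
        if cycle <= 12:
            return float(self._q_year1[self.arm][cycle - 1])
        if self.scenario == "lognormal":
            fit = self._lognormal_fit
            s_prev = float(fit.survival(float(cycle - 1)))
            s_now = float(fit.survival(float(cycle)))
            if s_prev <= 0:
                raise ParameterError(f"log-normal survival is 0 at month {cycle - 1}")
            return (s_prev - s_now) / s_prev
        return None

    def death_probs(self, cycle: int, occupancy: np.ndarray) -> np.ndarray:
        """Per-state monthly death probability for one cycle."""
        mp = self.ps.mortality_params
        rr = np.array(mp.severity_rr.as_tuple())

        q_overall = self.overall_prob(cycle)
        if q_overall is not None:
            mix = self._severity_mix(occupancy)
            q_sev = split_by_severity(q_overall, mix, rr)
        else:
            q_gp = self._genpop_monthly[cycle - 1]
            scalar = self.calibration_scalar(cycle)
            q_sev = np.minimum(1.0, rr * q_gp * scalar)

        by_sev = dict(zip(SEVERITIES, q_sev))
        out = np.zeros(N_STATES)
        for i, st in enumerate(STATES):
            if i == DEATH:
                continue
            q = by_sev[st.severity]
            if st.kind == "chronic":
                if st.history == "post_moderate":
                    q = min(1.0, q * mp.post_exac_rr_moderate)
                elif st.history == "post_severe":
                    q = min(1.0, q * mp.post_exac_rr_severe)
            elif st.kind == "tunnel_severe_exac":
                event = (
                    mp.severe_exac_mortality_year1
                    if cycle <= 12
                    else mp.severe_exac_mortality
                )
                q = q + (1.0 - q) * event
            out[i] = q
        return out

    def to_frame(self, occupancies: np.ndarray):
        """Audit export: probabilities for cycles 1..horizon given the
        occupancy path (rows = cycles, columns = canonical state order)."""
        import pandas as pd

        from .states import STATE_LABELS

        horizon = self.ps.horizon_months
        rows = [self.death_probs(t, occupancies[t - 1]) for t in range(1, horizon + 1)]
        df = pd.DataFrame(rows, columns=STATE_LABELS)
        df.insert(0, "cycle", np.arange(1, horizon + 1))
        return df


def build_schedule(
    ps: ParameterSet,
    arm: str,
    curves: dict[str, SurvivalCurve],
    life_table: LifeTable,
    scenario: str = "base",
) -> MortalitySchedule:
    """Construct the arm's mortality schedule (see :class:`MortalitySchedule`)."""
    return MortalitySchedule(ps, arm, curves, life_table, scenario)
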