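"""Typed parameter model for the COPD cost-effectiveness analysis.

Every input of the two-arm semi-Markov model lives in a :class:`ParameterSet`:
the baseline severity mix, monthly progression and exacerbation probabilities,
mortality inputs, utilities, unit costs, discounting and cohort demographics.
Values taken from the published evaluation carry ``provenance`` tag ``"published"``;
inputs the publication only reports in supplementary material are shipped as
documented synthetic defaults tagged ``"synthetic_default"``.

Probabilities are monthly unless a field name says otherwise; costs are GBP;
discount rates are annual fractions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import yaml

ARM_BGF = "BGF"
ARM_FF_UMEC_VI = "FF/UMEC/VI"
ARMS = (ARM_BGF, ARM_FF_UMEC_VI)

SEVERITIES = ("moderate", "severe", "very_severe")
HISTORIES = ("none", "post_moderate", "post_severe")


class ParameterError(ValueError):
    """Raised when an input falls outside its admissible range."""


@dataclass
class BySeverity:
    """A scalar per COPD severity level (GOLD 2 / 3 / 4)."""

    moderate: float
    severe: float
    very_severe: float

    def __getitem__(self, severity: str) -> float:
        return getattr(self, severity)

    def __iter__(self) -> Iterator[float]:
        return iter((self.moderate, self.severe, self.very_severe))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.moderate, self.severe, self.very_severe)


@dataclass
class ProgressionProbs:
    """Monthly probability of moving one severity level down the cascade."""

    mod_to_sev: float
    sev_to_vsev: float


@dataclass
class TransitionModel:
    """Severity-progression inputs.

    The trial-derived probabilities apply to the first model year and to all
    post-exacerbation strata; from cycle 13 onward, patients who never
    exacerbated progress at the slower rates observed in an exacerbation-free
    population. The comparator arm applies a relative risk versus BGF
    (assumed 1.00 for lack of head-to-head lung-function data).
    """

    trial_year1: ProgressionProbs
    no_exac_history: ProgressionProbs
    ffumecvi_rr: float = 1.0

    def monthly(self, history: str, cycle: int, arm: str) -> ProgressionProbs:
        """Progression probabilities for a history stratum at a given cycle."""
        if history == "none" and cycle >= 13:
            base = self.no_exac_history
        else:
            base = self.trial_year1
        if arm == ARM_BGF:
            return base
        rr = self.ffumecvi_rr
        return ProgressionProbs(
            min(1.0, base.mod_to_sev * rr), min(1.0, base.sev_to_vsev * rr)
        )


@dataclass
class ExacerbationProbs:
    """Monthly exacerbation probabilities per severity level (BGF arm).

    The comparator arm is expressed through relative risks versus BGF.
    ``post_exac_multiplier`` scales both probabilities in post-exacerbation
    strata (1.0 = no elevation of the re-exacerbation risk).
    """

    moderate_monthly: BySeverity
    severe_monthly: BySeverity
    ffumecvi_rr_moderate: float = 1.0
    ffumecvi_rr_severe: float = 1.0
    post_exac_multiplier: float = 1.0

    def monthly(self, severity: str, history: str, arm: str) -> tuple[float, float]:
        """Return (moderate, severe) exacerbation probabilities for a state."""
        p_mod = self.moderate_monthly[severity]
        p_sev = self.severe_monthly[severity]
        if arm != ARM_BGF:
            p_mod *= self.ffumecvi_rr_moderate
            p_sev *= self.ffumecvi_rr_severe
        if history != "none":
            p_mod *= self.post_exac_multiplier
            p_sev *= self.post_exac_multiplier
        return (min(1.0, p_mod), min(1.0, p_sev))


@dataclass
class MortalityParams:
    """Mortality inputs.

    ``severity_rr`` are relative risks versus annual general-population
    mortality; ``post_exac_rr`` multiply the no-history death probability in
    post-exacerbation states; ``severe_exac_mortality`` is the one-cycle event
    probability added in severe-exacerbation tunnel states beyond year 1 (set
    to 0 within year 1 to avoid double counting against trial mortality);
    ``constant_monthly_death`` feeds the constant-probability mortality mode.
    """

    severity_rr: BySeverity = field(
        default_factory=lambda: BySeverity(1.40, 2.60, 2.60)
    )
    post_exac_rr_moderate: float = 1.00
    post_exac_rr_severe: float = 1.00
    severe_exac_mortality: float = 0.12
    severe_exac_mortality_year1: float = 0.0
    constant_monthly_death: dict[str, float] = field(
        default_factory=lambda: {ARM_BGF: 0.00118, ARM_FF_UMEC_VI: 0.00193}
    )


@dataclass
class UtilitySet:
    """Health-state utilities and per-event exacerbation decrements."""

    severity_utility: BySeverity = field(
        default_factory=lambda: BySeverity(0.79, 0.76, 0.72)
    )
    moderate_exac_decrement: float = 0.055
    severe_exac_decrement: float = 0.090
    death_utility: float = 0.0


@dataclass
class CostSet:
    """Unit costs in GBP.

    Exacerbation event costs and the hospital end-of-life cost are published
    values; disease-management, acquisition, rescue, adverse-event and
    subsequent-treatment costs are synthetic defaults standing in for
    supplementary-table inputs, calibrated to the magnitude of the published
    per-arm cost totals.
    """

    disease_mgmt_monthly: BySeverity = field(
        default_factory=lambda: BySeverity(35.0, 48.0, 80.0)
    )
    moderate_exac_event: float = 53.23
    severe_exac_event: float = 3667.35
    acquisition_monthly: dict[str, float] = field(
        default_factory=lambda: {ARM_BGF: 44.50, ARM_FF_UMEC_VI: 44.50}
    )
    rescue_monthly: float = 5.00
    ae_one_time: dict[str, float] = field(
        default_factory=lambda: {ARM_BGF: 30.0, ARM_FF_UMEC_VI: 30.0}
    )
    subsequent_monthly: float = 71.50  # BGF + roflumilast
    end_of_life_hospital: float = 4028.0
    end_of_life_by_setting: dict[str, float] = field(
        default_factory=lambda: {
            "hospital": 4028.0,
            "home": 1500.0,
            "hospice": 3200.0,
            "care_home": 2600.0,
        }
    )
    end_of_life_setting_mix: dict[str, float] = field(
        default_factory=lambda: {
            "hospital": 0.55,
            "home": 0.25,
            "hospice": 0.10,
            "care_home": 0.10,
        }
    )

    def end_of_life_setting_weighted(self) -> float:
        return sum(
            self.end_of_life_by_setting[k] * w
            for k, w in self.end_of_life_setting_mix.items()
        )


@dataclass
class Discontinuation:
    """Monthly probability of discontinuing initial treatment.

    Trial-based rates apply during the first year; afterwards a flat 1% per
    cycle is used. Discontinued patients move to subsequent treatment
    (BGF + roflumilast) with unchanged efficacy, so only costs differ.
    """

    first_year_monthly: dict[str, float] = field(
        default_factory=lambda: {ARM_BGF: 0.020, ARM_FF_UMEC_VI: 0.020}
    )
    post_year1_monthly: float = 0.01

    def monthly(self, arm: str, cycle: int) -> float:
        if cycle <= 12:
            return self.first_year_monthly[arm]
        return self.post_year1_monthly


@dataclass
class ParameterSet:
    """Complete input set for a two-arm model run."""

    baseline_distribution: BySeverity = field(
        default_factory=lambda: BySeverity(0.285, 0.606, 0.109)
    )
    transition_probs: TransitionModel = field(
        default_factory=lambda: TransitionModel(
            trial_year1=ProgressionProbs(0.0227, 0.0060),
            no_exac_history=ProgressionProbs(0.0113, 0.0087),
            ffumecvi_rr=1.0,
        )
    )
    exacerbation_probs: ExacerbationProbs = field(
        default_factory=lambda: ExacerbationProbs(
            moderate_monthly=BySeverity(0.050, 0.060, 0.070),
            severe_monthly=BySeverity(0.003, 0.005, 0.008),
        )
    )
    mortality_params: MortalityParams = field(default_factory=MortalityParams)
    utilities: UtilitySet = field(default_factory=UtilitySet)
    costs: CostSet = field(default_factory=CostSet)
    discontinuation: Discontinuation = field(default_factory=Discontinuation)
    discount_rate_costs: float = 0.035
    discount_rate_outcomes: float = 0.035
    wtp_threshold: float = 20000.0
    baseline_age: int = 65
    proportion_female: float = 0.40
    horizon_months: int = 60
    mortality_mode: str = "km_curve"  # or "constant"
    half_cycle_correction: bool = False
    lump_sum_decrements: bool = False

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        def _build(klass, payload):
            kwargs = {}
            for f in dataclasses.fields(klass):
                if f.name not in payload:
                    continue
                value = payload[f.name]
                sub = _NESTED.get((klass, f.name))
                if sub is not None and isinstance(value, dict):
                    value = _build(sub, value)
                kwargs[f.name] = value
            return klass(**kwargs)

        return _build(cls, data)

    def copy(self) -> "ParameterSet":
        return ParameterSet.from_dict(self.to_dict())


_NESTED = {
    (ParameterSet, "baseline_distribution"): BySeverity,
    (ParameterSet, "transition_probs"): TransitionModel,
    (ParameterSet, "exacerbation_probs"): ExacerbationProbs,
    (ParameterSet, "mortality_params"): MortalityParams,
    (ParameterSet, "utilities"): UtilitySet,
    (ParameterSet, "costs"): CostSet,
    (ParameterSet, "discontinuation"): Discontinuation,
    (TransitionModel, "trial_year1"): ProgressionProbs,
    (TransitionModel, "no_exac_history"): ProgressionProbs,
    (ExacerbationProbs, "moderate_monthly"): BySeverity,
    (ExacerbationProbs, "severe_monthly"): BySeverity,
    (MortalityParams, "severity_rr"): BySeverity,
    (UtilitySet, "severity_utility"): BySeverity,
    (CostSet, "disease_mgmt_monthly"): BySeverity,
}

#: Provenance of every default, keyed by dot-path. ``published`` = printed in the
#: publication's main text; ``synthetic_default`` = documented stand-in for a
#: supplementary-only input.
PROVENANCE: dict[str, str] = {
    "baseline_distribution": "published",
    "transition_probs.trial_year1": "published",
    "transition_probs.no_exac_history": "published",
    "transition_probs.ffumecvi_rr": "published",
    "exacerbation_probs.moderate_monthly": "synthetic_default",
    "exacerbation_probs.severe_monthly": "synthetic_default",
    "exacerbation_probs.ffumecvi_rr_moderate": "synthetic_default",
    "exacerbation_probs.ffumecvi_rr_severe": "synthetic_default",
    "exacerbation_probs.post_exac_multiplier": "synthetic_default",
    "mortality_params.severity_rr": "published",
    "mortality_params.post_exac_rr_moderate": "published",
    "mortality_params.post_exac_rr_severe": "published",
    "mortality_params.severe_exac_mortality": "published",
    "mortality_params.severe_exac_mortality_year1": "published",
    "mortality_params.constant_monthly_death": "published",
    "utilities.severity_utility": "published",
    "utilities.moderate_exac_decrement": "published",
    "utilities.severe_exac_decrement": "published",
    "costs.disease_mgmt_monthly": "synthetic_default",
    "costs.moderate_exac_event": "published",
    "costs.severe_exac_event": "published",
    "costs.acquisition_monthly": "synthetic_default",
    "costs.rescue_monthly": "synthetic_default",
    "costs.ae_one_time": "synthetic_default",
    "costs.subsequent_monthly": "synthetic_default",
    "costs.end_of_life_hospital": "published",
    "costs.end_of_life_by_setting": "synthetic_default",
    "costs.end_of_life_setting_mix": "synthetic_default",
    "discontinuation.first_year_monthly": "synthetic_default",
    "discontinuation.post_year1_monthly": "published",
    "discount_rate_costs": "published",
    "discount_rate_outcomes": "published",
    "wtp_threshold": "published",
    "baseline_age": "synthetic_default",
    "proportion_female": "synthetic_default",
    "horizon_months": "published",
}


# ---------------------------------------------------------------------------
# Probability / rate conversions
# ---------------------------------------------------------------------------


def period_prob_to_monthly(p: float, n_months: float) -> float:
    """Convert a probability over an ``n_months`` period to a monthly one.

    Uses the constant-rate identity ``1 - (1 - p)**(1/n)``; converting a
    52-week trial probability to the one-month cycle uses ``n_months=12``
    (twelve cycles per 52 trial weeks).
    """
    if not 0.0 <= p < 1.0:
        raise ParameterError(f"period probability p={p!r} must be in [0, 1)")
    if n_months <= 0:
        raise ParameterError(f"n_months={n_months!r} must be positive")
    return 1.0 - (1.0 - p) ** (1.0 / n_months)


def combine_severe_exac_mortality(in_hospital: float, post_discharge: float) -> float:
    """Combine in-hospital and post-discharge death probabilities.

    Returns ``a + (1 - a) * b`` — death in hospital, or survival to discharge
    followed by death within the post-discharge window.
    """
    for name, v in (("in_hospital", in_hospital), ("post_discharge", post_discharge)):
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name}={v!r} must be in [0, 1]")
    return in_hospital + (1.0 - in_hospital) * post_discharge


def discount_factor(annual_rate: float, cycle: int) -> float:
    """Monthly-compounded discount factor ``(1 + r)**(-cycle/12)``."""
    if annual_rate < 0:
        raise ParameterError(f"annual_rate={annual_rate!r} must be >= 0")
    if cycle == 0:
        return 1.0
    return (1.0 + annual_rate) ** (-cycle / 12.0)


# ---------------------------------------------------------------------------
# Defaults and validation
# ---------------------------------------------------------------------------


def default_parameters() -> ParameterSet:
    """The default input set: main-text values plus documented synthetic
    stand-ins for supplementary-only inputs (see :data:`PROVENANCE`)."""
    return ParameterSet()


def _prob(name, v, out):
    if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
        out.append(f"{name}={v!r}: probability must be in [0, 1]")


def _nonneg(name, v, out):
    if not (isinstance(v, (int, float)) and v >= 0.0):
        out.append(f"{name}={v!r}: must be >= 0")


def _positive(name, v, out):
    if not (isinstance(v, (int, float)) and v > 0.0):
        out.append(f"{name}={v!r}: must be > 0")


def validate_parameters(ps: ParameterSet) -> list[str]:
    """Check every type invariant; returns a list of violations (never raises)."""
    out: list[str] = []

    total = sum(ps.baseline_distribution)
    if abs(total - 1.0) > 1e-9:
        out.append(
            f"baseline_distribution={ps.baseline_distribution.as_tuple()!r}: "
            f"sums to {total}, must sum to 1"
        )
    for s in SEVERITIES:
        _prob(f"baseline_distribution.{s}", ps.baseline_distribution[s], out)

    tp = ps.transition_probs
    for stratum in ("trial_year1", "no_exac_history"):
        pp = getattr(tp, stratum)
        _prob(f"transition_probs.{stratum}.mod_to_sev", pp.mod_to_sev, out)
        _prob(f"transition_probs.{stratum}.sev_to_vsev", pp.sev_to_vsev, out)
    _positive("transition_probs.ffumecvi_rr", tp.ffumecvi_rr, out)

    ep = ps.exacerbation_probs
    for s in SEVERITIES:
        _prob(f"exacerbation_probs.moderate_monthly.{s}", ep.moderate_monthly[s], out)
        _prob(f"exacerbation_probs.severe_monthly.{s}", ep.severe_monthly[s], out)
    _positive("exacerbation_probs.ffumecvi_rr_moderate", ep.ffumecvi_rr_moderate, out)
    _positive("exacerbation_probs.ffumecvi_rr_severe", ep.ffumecvi_rr_severe, out)
    _positive("exacerbation_probs.post_exac_multiplier", ep.post_exac_multiplier, out)

    mp = ps.mortality_params
    for s in SEVERITIES:
        _positive(f"mortality_params.severity_rr.{s}", mp.severity_rr[s], out)
    _positive("mortality_params.post_exac_rr_moderate", mp.post_exac_rr_moderate, out)
    _positive("mortality_params.post_exac_rr_severe", mp.post_exac_rr_severe, out)
    _prob("mortality_params.severe_exac_mortality", mp.severe_exac_mortality, out)
    _prob(
        "mortality_params.severe_exac_mortality_year1",
        mp.severe_exac_mortality_year1,
        out,
    )
    for arm, q in mp.constant_monthly_death.items():
        _prob(f"mortality_params.constant_monthly_death[{arm}]", q, out)

    ut = ps.utilities
    for s in SEVERITIES:
        u = ut.severity_utility[s]
        if not 0.0 <= u <= 1.0:
            out.append(f"utilities.severity_utility.{s}={u!r}: must be in [0, 1]")
    _nonneg("utilities.moderate_exac_decrement", ut.moderate_exac_decrement, out)
    _nonneg("utilities.severe_exac_decrement", ut.severe_exac_decrement, out)
    for s in SEVERITIES:
        for dec_name, dec in (
            ("moderate_exac_decrement", ut.moderate_exac_decrement),
            ("severe_exac_decrement", ut.severe_exac_decrement),
        ):
            if dec >= ut.severity_utility[s] >= 0:
                out.append(
                    f"utilities.{dec_name}={dec!r}: decrement must be smaller than "
                    f"severity_utility.{s}={ut.severity_utility[s]!r}"
                )

    cs = ps.costs
    for s in SEVERITIES:
        _nonneg(f"costs.disease_mgmt_monthly.{s}", cs.disease_mgmt_monthly[s], out)
    _nonneg("costs.moderate_exac_event", cs.moderate_exac_event, out)
    _nonneg("costs.severe_exac_event", cs.severe_exac_event, out)
    for arm, c in cs.acquisition_monthly.items():
        _nonneg(f"costs.acquisition_monthly[{arm}]", c, out)
    _nonneg("costs.rescue_monthly", cs.rescue_monthly, out)
    for arm, c in cs.ae_one_time.items():
        _nonneg(f"costs.ae_one_time[{arm}]", c, out)
    _nonneg("costs.subsequent_monthly", cs.subsequent_monthly, out)
    _nonneg("costs.end_of_life_hospital", cs.end_of_life_hospital, out)
    for k, c in cs.end_of_life_by_setting.items():
        _nonneg(f"costs.end_of_life_by_setting[{k}]", c, out)
    mix_total = sum(cs.end_of_life_setting_mix.values())
    if abs(mix_total - 1.0) > 1e-9:
        out.append(
            f"costs.end_of_life_setting_mix: sums to {mix_total}, must sum to 1"
        )

    dc = ps.discontinuation
    for arm, d in dc.first_year_monthly.items():
        _prob(f"discontinuation.first_year_monthly[{arm}]", d, out)
    _prob("discontinuation.post_year1_monthly", dc.post_year1_monthly, out)

    _nonneg("discount_rate_costs", ps.discount_rate_costs, out)
    _nonneg("discount_rate_outcomes", ps.discount_rate_outcomes, out)
    _nonneg("wtp_threshold", ps.wtp_threshold, out)
    _prob("proportion_female", ps.proportion_female, out)
    if not (isinstance(ps.horizon_months, int) and ps.horizon_months >= 1):
        out.append(f"horizon_months={ps.horizon_months!r}: must be an integer >= 1")
    if ps.mortality_mode not in ("km_curve", "constant"):
        out.append(
            f"mortality_mode={ps.mortality_mode!r}: must be 'km_curve' or 'constant'"
        )
    return out


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a ParameterSet from YAML or JSON (detected by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return ParameterSet.from_dict(data)


def save_parameters(ps: ParameterSet, path: str | Path) -> None:
    path = Path(path)
    data = ps.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def parameter_schema() -> dict:
    """The machine-readable JSON schema shipped with the package."""
    with resources.files("copdcem").joinpath("parameter_schema.json").open() as fh:
        return json.load(fh)
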