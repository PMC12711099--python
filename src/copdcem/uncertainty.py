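"""One-way deterministic sensitivity analysis, probabilistic sensitivity
analysis and the named scenario runner.

Parameters are addressed by dot-paths into the :class:`ParameterSet`
(``costs.severe_exac_event``, ``utilities.severity_utility.moderate``,
``mortality_params.constant_monthly_death.BGF`` ...). The DSA varies each
addressed scalar by ±20% of its base value, clamping probability-like
quantities into [0, 1]; the PSA draws probabilities and utilities from Beta,
costs from Gamma and relative risks from log-normal distributions, moment
matched to mean = base value and SE = 20% of the base unless overridden.
Parameters are sampled independently.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ComparisonResults, ModelInputs, default_model_inputs, run_comparison
from .mortality import SCENARIOS
from .parameters import ParameterError, ParameterSet, validate_parameters

logger = logging.getLogger(__name__)

DSA_FRACTION = 0.20
PSA_SE_FRACTION = 0.20


# ---------------------------------------------------------------------------
# Dot-path access
# ---------------------------------------------------------------------------


def _descend(obj, parts: list[str]):
    for j, part in enumerate(parts):
        if dataclasses.is_dataclass(obj):
            if not hasattr(obj, part):
                raise ParameterError(_unknown_path(".".join(parts)))
            obj = getattr(obj, part)
        elif isinstance(obj, dict):
            if part not in obj:
                raise ParameterError(_unknown_path(".".join(parts)))
            obj = obj[part]
        else:
            raise ParameterError(_unknown_path(".".join(parts)))
    return obj


def _unknown_path(path: str) -> str:
    return (
        f"unknown parameter id {path!r}; valid ids are dot-paths such as "
        + ", ".join(default_dsa_parameters()[:4])
        + ", ..."
    )


def get_param(ps: ParameterSet, path: str) -> float:
    value = _descend(ps, path.split("."))
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ParameterError(f"parameter id {path!r} does not address a scalar")
    return float(value)


def set_param(ps: ParameterSet, path: str, value: float) -> None:
    parts = path.split(".")
    parent = _descend(ps, parts[:-1])
    leaf = parts[-1]
    if dataclasses.is_dataclass(parent):
        if not hasattr(parent, leaf):
            raise ParameterError(_unknown_path(path))
        setattr(parent, leaf, value)
    elif isinstance(parent, dict):
        if leaf not in parent:
            raise ParameterError(_unknown_path(path))
        parent[leaf] = value
    else:
        raise ParameterError(_unknown_path(path))


def classify_parameter(path: str) -> str:
    """Distribution family / clamping class for a parameter path."""
    if path.startswith("costs."):
        return "cost"
    if any("rr" in part for part in path.split(".")) or "hazard_ratio" in path:
        return "relative_risk"
    if path.startswith("utilities.severity_utility"):
        return "probability"  # utilities live in [0, 1]
    if "decrement" in path:
        return "probability"
    if "multiplier" in path:
        return "relative_risk"
    return "probability"


# ---------------------------------------------------------------------------
# One-way DSA
# ---------------------------------------------------------------------------


@dataclass
class TornadoRecord:
    parameter: str
    low_value: float
    high_value: float
    inb_low: float
    inb_high: float
    icur_low: float | str | None
    icur_high: float | str | None

    @property
    def spread(self) -> float:
        return abs(self.inb_high - self.inb_low)


def default_dsa_parameters() -> list[str]:
    """A practical default set of one-way DSA parameters."""
    ids = [
        "costs.subsequent_monthly",
        "costs.severe_exac_event",
        "costs.moderate_exac_event",
        "costs.end_of_life_hospital",
        "costs.rescue_monthly",
        "costs.acquisition_monthly.BGF",
        "costs.acquisition_monthly.FF/UMEC/VI",
        "utilities.severity_utility.moderate",
        "utilities.severity_utility.severe",
        "utilities.moderate_exac_decrement",
        "utilities.severe_exac_decrement",
        "exacerbation_probs.severe_monthly.severe",
        "exacerbation_probs.severe_monthly.very_severe",
        "exacerbation_probs.moderate_monthly.severe",
        "exacerbation_probs.ffumecvi_rr_severe",
        "mortality_params.severe_exac_mortality",
        "discontinuation.first_year_monthly.BGF",
        "discontinuation.first_year_monthly.FF/UMEC/VI",
        "discontinuation.post_year1_monthly",
    ]
    for s in ("moderate", "severe", "very_severe"):
        ids.append(f"costs.disease_mgmt_monthly.{s}")
    return ids


def _clamped_bounds(path: str, base: float) -> tuple[float, float]:
    low = base * (1.0 - DSA_FRACTION)
    high = base * (1.0 + DSA_FRACTION)
    if classify_parameter(path) == "probability" and high > 1.0:
        logger.warning("DSA bound for %s clamped from %s to 1.0", path, high)
        high = 1.0
    return low, high


def one_way_dsa(
    ps: ParameterSet,
    parameter_ids: list[str] | None = None,
    inputs: ModelInputs | None = None,
    scenario: str = "base",
) -> list[TornadoRecord]:
    """Run the full two-arm model at ±20% bounds of each parameter,
    holding everything else fixed; records sorted by INB spread."""
    if parameter_ids is None:
        parameter_ids = default_dsa_parameters()
    if inputs is None:
        inputs = default_model_inputs(ps)

    records = []
    for path in parameter_ids:
        base = get_param(ps, path)
        low, high = _clamped_bounds(path, base)
        outcomes = {}
        for bound, value in (("low", low), ("high", high)):
            trial = ps.copy()
            set_param(trial, path, value)
            res = run_comparison(trial, inputs, scenario=scenario)
            outcomes[bound] = res.incremental
        records.append(
            TornadoRecord(
                parameter=path,
                low_value=low,
                high_value=high,
                inb_low=outcomes["low"].inb_at_threshold,
                inb_high=outcomes["high"].inb_at_threshold,
                icur_low=outcomes["low"].icur_per_qaly,
                icur_high=outcomes["high"].icur_per_qaly,
            )
        )
    records.sort(key=lambda r: (-r.spread, r.parameter))
    return records


def tornado_frame(records: list[TornadoRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "low": r.low_value,
                "high": r.high_value,
                "outcome_low": r.inb_low,
                "outcome_high": r.inb_high,
                "spread": r.spread,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------


def psa_parameter_paths(ps: ParameterSet) -> list[str]:
    """Default set of independently sampled PSA parameters."""
    paths = [
        "transition_probs.trial_year1.mod_to_sev",
        "transition_probs.trial_year1.sev_to_vsev",
        "transition_probs.no_exac_history.mod_to_sev",
        "transition_probs.no_exac_history.sev_to_vsev",
        "transition_probs.ffumecvi_rr",
        "exacerbation_probs.ffumecvi_rr_moderate",
        "exacerbation_probs.ffumecvi_rr_severe",
        "mortality_params.severity_rr.moderate",
        "mortality_params.severity_rr.severe",
        "mortality_params.severity_rr.very_severe",
        "mortality_params.severe_exac_mortality",
        "mortality_params.constant_monthly_death.BGF",
        "mortality_params.constant_monthly_death.FF/UMEC/VI",
        "utilities.severity_utility.moderate",
        "utilities.severity_utility.severe",
        "utilities.severity_utility.very_severe",
        "utilities.moderate_exac_decrement",
        "utilities.severe_exac_decrement",
        "costs.moderate_exac_event",
        "costs.severe_exac_event",
        "costs.subsequent_monthly",
        "costs.rescue_monthly",
        "costs.end_of_life_hospital",
        "costs.acquisition_monthly.BGF",
        "costs.acquisition_monthly.FF/UMEC/VI",
        "discontinuation.first_year_monthly.BGF",
        "discontinuation.first_year_monthly.FF/UMEC/VI",
        "discontinuation.post_year1_monthly",
    ]
    for s in ("moderate", "severe", "very_severe"):
        paths.append(f"exacerbation_probs.moderate_monthly.{s}")
        paths.append(f"exacerbation_probs.severe_monthly.{s}")
        paths.append(f"costs.disease_mgmt_monthly.{s}")
    return paths


def sample_beta(rng: np.random.Generator, mean: float, se: float) -> float:
    if se == 0 or mean in (0.0, 1.0):
        return mean
    nu = mean * (1.0 - mean) / se**2 - 1.0
    if nu <= 0:
        logger.warning(
            "Beta moment matching infeasible (mean=%s, se=%s); clipped normal", mean, se
        )
        return float(np.clip(rng.normal(mean, se), 0.0, 1.0))
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def sample_gamma(rng: np.random.Generator, mean: float, se: float) -> float:
    if se == 0 or mean == 0:
        return mean
    shape = (mean / se) ** 2
    scale = se**2 / mean
    return float(rng.gamma(shape, scale))


def sample_lognormal(rng: np.random.Generator, mean: float, se: float) -> float:
    if se == 0 or mean == 0:
        return mean
    sigma2 = np.log(1.0 + (se / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


_SAMPLERS = {
    "probability": sample_beta,
    "cost": sample_gamma,
    "relative_risk": sample_lognormal,
}


@dataclass
class PsaDraw:
    index: int
    params: ParameterSet
    delta_cost: float = float("nan")
    delta_qalys: float = float("nan")


def psa_sample(
    ps: ParameterSet,
    seed: int,
    se_fraction: float = PSA_SE_FRACTION,
    se_overrides: dict[str, float] | None = None,
    paths: list[str] | None = None,
) -> PsaDraw:
    """Draw one sampled ParameterSet; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    draw = ps.copy()
    overrides = se_overrides or {}
    for path in paths if paths is not None else psa_parameter_paths(ps):
        base = get_param(ps, path)
        se = overrides.get(path, se_fraction * abs(base))
        sampler = _SAMPLERS[classify_parameter(path)]
        set_param(draw, path, sampler(rng, base, se))
    violations = validate_parameters(draw)
    if violations:
        raise ParameterError(f"PSA draw failed validation: {violations}")
    return PsaDraw(index=seed, params=draw)


@dataclass
class PsaResults:
    points: pd.DataFrame  # columns: draw, delta_cost, delta_qalys
    ceac: pd.DataFrame  # columns: threshold, probability

    def ceac_at(self, threshold: float) -> float:
        row = self.ceac[self.ceac["threshold"] == threshold]
        if row.empty:
            raise ParameterError(f"threshold {threshold} not on the CEAC grid")
        return float(row["probability"].iloc[0])


def default_threshold_grid() -> np.ndarray:
    return np.arange(0.0, 50001.0, 2500.0)


def run_psa(
    ps: ParameterSet,
    n: int,
    seed: int,
    inputs: ModelInputs | None = None,
    thresholds: np.ndarray | None = None,
    se_fraction: float = PSA_SE_FRACTION,
    se_overrides: dict[str, float] | None = None,
) -> PsaResults:
    """Monte-Carlo PSA: cost-effectiveness plane points and the CEAC.

    ``CEAC(lambda)`` is the fraction of draws with positive incremental net
    benefit at willingness-to-pay ``lambda``; the grid always contains the
    parameter set's own threshold.
    """
    if n < 1:
        raise ParameterError(f"n={n!r} must be >= 1")
    if inputs is None:
        inputs = default_model_inputs(ps)
    if thresholds is None:
        thresholds = default_threshold_grid()
    thresholds = np.union1d(np.asarray(thresholds, dtype=float), [ps.wtp_threshold])

    root = np.random.SeedSequence(seed)
    child_seeds = root.generate_state(n, dtype=np.uint32)

    rows = []
    for i in range(n):
        draw = psa_sample(
            ps,
            int(child_seeds[i]),
            se_fraction=se_fraction,
            se_overrides=se_overrides,
        )
        res = run_comparison(draw.params, inputs)
        rows.append(
            {
                "draw": i,
                "delta_cost": res.incremental.delta_cost,
                "delta_qalys": res.incremental.delta_qalys,
            }
        )
    points = pd.DataFrame(rows)

    dc = points["delta_cost"].to_numpy()
    dq = points["delta_qalys"].to_numpy()
    ceac = pd.DataFrame(
        {
            "threshold": thresholds,
            "probability": [float(np.mean(lam * dq - dc > 0)) for lam in thresholds],
        }
    )
    return PsaResults(points=points, ceac=ceac)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


def run_scenario(
    name: str, ps: ParameterSet, inputs: ModelInputs | None = None
) -> ComparisonResults:
    """Run one named scenario: base, waning, lognormal or eol_setting."""
    if name not in SCENARIOS:
        raise ParameterError(
            f"unknown scenario {name!r}; valid scenarios: {', '.join(SCENARIOS)}"
        )
    return run_comparison(ps, inputs, scenario=name)
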