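"""Synthetic stand-ins for externally sourced model inputs.

The published evaluation drives first-year mortality from digitized,
MAIC-adjusted Kaplan–Meier curves and background mortality from national
lifetables; neither is deposited in machine-readable form. This module
generates parametric substitutes so every downstream stage is runnable and
testable: an exponential (or log-normal) cumulative-mortality curve pair
linked by a configurable hazard ratio (default 0.61, BGF vs FF/UMEC/VI),
and a Gompertz–Makeham age/sex life table.

All generated objects assert their own type invariants on construction and
round-trip through plain CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .parameters import ARM_BGF, ARM_FF_UMEC_VI, ParameterError


@dataclass
class SurvivalCurve:
    """Arm-level cumulative all-cause mortality sampled on a monthly grid.

    ``cumulative_mortality[t]`` is the fraction dead by month ``t``;
    index 0 is model start (always 0).
    """

    month: np.ndarray
    cumulative_mortality: np.ndarray
    arm_label: str = ""

    def __post_init__(self) -> None:
        self.month = np.asarray(self.month, dtype=int)
        self.cumulative_mortality = np.asarray(self.cumulative_mortality, dtype=float)
        if self.month.shape != self.cumulative_mortality.shape:
            raise ParameterError("month and cumulative_mortality lengths differ")
        m = self.cumulative_mortality
        if m[0] != 0.0:
            raise ParameterError("cumulative mortality at month 0 must be 0")
        if np.any(np.diff(m) < 0):
            raise ParameterError("cumulative mortality must be non-decreasing")
        if np.any(m >= 1.0) or np.any(m < 0.0):
            raise ParameterError("cumulative mortality must lie in [0, 1)")

    @property
    def max_month(self) -> int:
        return int(self.month[-1])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"month": self.month, "cumulative_mortality": self.cumulative_mortality}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, arm_label: str = "") -> "SurvivalCurve":
        df = pd.read_csv(path)
        return cls(
            month=df["month"].to_numpy(),
            cumulative_mortality=df["cumulative_mortality"].to_numpy(),
            arm_label=arm_label,
        )


@dataclass
class LifeTable:
    """Annual death probabilities by single year of age and sex."""

    age: np.ndarray
    qx_male: np.ndarray
    qx_female: np.ndarray

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=int)
        self.qx_male = np.asarray(self.qx_male, dtype=float)
        self.qx_female = np.asarray(self.qx_female, dtype=float)
        for name, q in (("qx_male", self.qx_male), ("qx_female", self.qx_female)):
            bad = np.where((q < 0) | (q > 1))[0]
            if bad.size:
                raise ParameterError(
                    f"{name} out of [0, 1] at age {int(self.age[bad[0]])}"
                )

    @property
    def min_age(self) -> int:
        return int(self.age[0])

    @property
    def max_age(self) -> int:
        return int(self.age[-1])

    def qx(self, age: int, sex: str) -> float:
        age = min(max(age, self.min_age), self.max_age)  # clamp at table edges
        idx = age - self.min_age
        return float(self.qx_male[idx] if sex == "male" else self.qx_female[idx])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"age": self.age, "qx_male": self.qx_male, "qx_female": self.qx_female}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(
            age=df["age"].to_numpy(),
            qx_male=df["qx_male"].to_numpy(),
            qx_female=df["qx_female"].to_numpy(),
        )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

#: Monthly hazard calibrated so the reference (FF/UMEC/VI) curve reproduces
#: the published constant monthly death probability of 0.193%.
DEFAULT_REF_MONTHLY_HAZARD = -math.log(1.0 - 0.00193)
DEFAULT_HAZARD_RATIO = 0.61


def make_km_pair(
    ref_monthly_hazard: float = DEFAULT_REF_MONTHLY_HAZARD,
    hazard_ratio: float = DEFAULT_HAZARD_RATIO,
    months: int = 60,
    shape: str = "exponential",
    lognormal_mu: float = 4.0,
    lognormal_sigma: float = 1.5,
) -> dict[str, SurvivalCurve]:
    """Generate the two-arm cumulative mortality curve pair.

    The reference arm is FF/UMEC/VI; the intervention arm (BGF) applies the
    hazard ratio to the reference cumulative hazard, so under the default
    exponential shape ``M_ref(t) = 1 - exp(-h t)`` and
    ``M_int(t) = 1 - exp(-h·HR·t)``. The ``lognormal`` shape gives the
    reference arm survival ``S(t) = 1 - Phi((ln t - mu)/sigma)`` with the
    intervention arm again via proportional hazards (``S_int = S_ref**HR``).
    """
    if ref_monthly_hazard <= 0:
        raise ParameterError(f"ref_monthly_hazard={ref_monthly_hazard!r} must be > 0")
    if hazard_ratio <= 0:
        raise ParameterError(f"hazard_ratio={hazard_ratio!r} must be > 0")
    if months < 1:
        raise ParameterError(f"months={months!r} must be >= 1")

    t = np.arange(months + 1, dtype=float)
    if shape == "exponential":
        s_ref = np.exp(-ref_monthly_hazard * t)
    elif shape == "lognormal":
        s_ref = np.ones_like(t)
        s_ref[1:] = norm.sf((np.log(t[1:]) - lognormal_mu) / lognormal_sigma)
    else:
        raise ParameterError(f"unknown curve shape {shape!r}")
    s_int = s_ref**hazard_ratio

    return {
        ARM_BGF: SurvivalCurve(t, 1.0 - s_int, arm_label=ARM_BGF),
        ARM_FF_UMEC_VI: SurvivalCurve(t, 1.0 - s_ref, arm_label=ARM_FF_UMEC_VI),
    }


#: Gompertz–Makeham defaults per sex: annual hazard a + b * exp(c * age).
#: Calibrated so male mortality exceeds female at every age and so the
#: severity-adjusted general-population hazard sits below the trial cohort's
#: month-12 hazard — the regime in which the model's hazard-ratio
#: extrapolation anchor is informative (scalar > 1 for both arms).
DEFAULT_MAKEHAM = {
    "male": (1.2e-4, 8.0e-6, 0.10),
    "female": (8.0e-5, 5.5e-6, 0.10),
}


def make_life_table(
    baseline_age: int = 40,
    max_age: int = 110,
    makeham: dict[str, tuple[float, float, float]] | None = None,
) -> LifeTable:
    """Generate a synthetic life table from Gompertz–Makeham hazards.

    ``qx(age) = 1 - exp(-(a + b * exp(c * age)))`` per sex. Defaults yield
    male qx >= female qx at every age and strictly increasing qx with age.
    """
    if baseline_age >= max_age:
        raise ParameterError("baseline_age must be below max_age")
    params = makeham or DEFAULT_MAKEHAM
    ages = np.arange(baseline_age, max_age + 1)
    cols = {}
    for sex in ("male", "female"):
        a, b, c = params[sex]
        hazard = a + b * np.exp(c * ages.astype(float))
        q = 1.0 - np.exp(-hazard)
        bad = np.where((q < 0) | (q > 1))[0]
        if bad.size:
            raise ParameterError(
                f"generated qx out of range at age {int(ages[bad[0]])} for {sex}"
            )
        cols[sex] = q
    return LifeTable(age=ages, qx_male=cols["male"], qx_female=cols["female"])


def add_sampling_noise(
    curve: SurvivalCurve, n_at_risk: int, seed: int
) -> SurvivalCurve:
    """Binomially perturb a curve as if estimated from ``n_at_risk`` patients.

    Each month's conditional death probability is replaced by the empirical
    fraction among the surviving simulated patients; the output is a valid
    non-decreasing curve and is deterministic given ``seed``.
    """
    if n_at_risk < 1:
        raise ParameterError(f"n_at_risk={n_at_risk!r} must be >= 1")
    rng = np.random.default_rng(seed)
    m = curve.cumulative_mortality
    alive = n_at_risk
    noisy = np.zeros_like(m)
    for t in range(1, len(m)):
        surv_prev = 1.0 - m[t - 1]
        q = 0.0 if surv_prev <= 0 else (m[t] - m[t - 1]) / surv_prev
        deaths = rng.binomial(alive, min(max(q, 0.0), 1.0)) if alive > 0 else 0
        alive -= deaths
        noisy[t] = 1.0 - alive / n_at_risk
    # guard against an all-dead tail, which would violate the < 1 invariant
    noisy = np.minimum(noisy, 1.0 - 0.5 / n_at_risk)
    noisy = np.maximum.accumulate(noisy)
    return SurvivalCurve(curve.month.copy(), noisy, arm_label=curve.arm_label)
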