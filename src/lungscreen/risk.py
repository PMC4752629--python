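"""Absolute lung-cancer risk model and eligibility gate.

Implements the structure of the Liverpool Lung Project (LLP)-style risk
model used to select screening participants: a multivariable logistic
linear predictor over risk factors (smoking duration, respiratory disease
history, asbestos exposure, prior malignancy, family history of lung
cancer), converted to a 5-year absolute risk by scaling age/sex-specific
incidence and accumulating hazard over the coming five years:

    RR       = exp(linear_predictor - intercept)
    risk_5yr = 1 - exp( - sum_{t=0..4} h(age + t, sex) * RR / mean_RR )

where ``h`` is the annual incidence treated as a hazard and ``mean_RR`` is
the population-average relative risk used for normalisation.  Individuals
with a 5-year risk at or above the gate threshold (5% by default) are
eligible for screening.

The published model's coefficient values are not reproduced here; the
packaged defaults are an illustrative configuration with the same factor
structure, and both coefficients and incidence are ordinary config inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .cohort import RiskFactorProfile

__all__ = [
    "LLPCoefficients",
    "IncidenceTable",
    "RiskScore",
    "smoking_duration_band",
    "linear_predictor",
    "absolute_risk_5yr",
    "eligibility_gate",
    "score_profiles",
    "default_coefficients",
    "default_incidence",
]

ELIGIBILITY_THRESHOLD = 0.05


def smoking_duration_band(years: int) -> str:
    """Categorical smoking-duration band used by the linear predictor."""
    if years < 0:
        raise ValueError("smoking duration must be >= 0")
    if years == 0:
        return "0"
    if years <= 20:
        return "1-20"
    if years <= 40:
        return "21-40"
    return "41+"


@dataclass(frozen=True)
class LLPCoefficients:
    """Logistic-model coefficients: intercept plus per-factor log odds ratios.

    ``terms`` maps factor name -> {level: log-OR}.  Reference levels carry
    coefficient 0 and must be present, so every profile level can be
    resolved; an unknown level is an error, not a silent zero.
    """

    intercept: float
    terms: dict[str, dict[str, float]]

    REQUIRED_FACTORS = (
        "smoking_duration_band",
        "respiratory_disease",
        "asbestos_exposure",
        "prior_malignancy",
        "family_history",
    )

    def __post_init__(self) -> None:
        missing = [f for f in self.REQUIRED_FACTORS if f not in self.terms]
        if missing:
            raise ValueError(f"coefficients missing factors: {missing}")

    def lookup(self, factor: str, level: str) -> float:
        try:
            levels = self.terms[factor]
        except KeyError:
            raise KeyError(f"unknown factor {factor!r}") from None
        try:
            return float(levels[level])
        except KeyError:
            raise KeyError(
                f"factor {factor!r} has no coefficient for level {level!r}"
            ) from None


def default_coefficients() -> LLPCoefficients:
    """Illustrative coefficient set (not the published model's values).

    Magnitudes are chosen to be epidemiologically plausible for these
    factors (log odds ratios in the 0.3–2.3 range, strongest for long
    smoking duration) so that heavy-exposure profiles at ages 60+ clear the
    5% gate under :func:`default_incidence`.
    """
    return LLPCoefficients(
        intercept=-6.0,
        terms={
            "smoking_duration_band": {"0": 0.0, "1-20": 0.8, "21-40": 1.5, "41+": 2.3},
            "respiratory_disease": {"no": 0.0, "yes": 0.45},
            "asbestos_exposure": {"no": 0.0, "yes": 0.35},
            "prior_malignancy": {"no": 0.0, "yes": 0.50},
            "family_history": {"none": 0.0, "early": 0.75, "late": 0.40},
        },
    )


@dataclass(frozen=True)
class IncidenceTable:
    """Age-band and sex specific annual lung-cancer incidence per 100 000.

    Bands are half-open ``[age_low, age_high)``, contiguous per sex.
    """

    table: pd.DataFrame  # columns: age_low, age_high, sex, rate_per_100k

    def __post_init__(self) -> None:
        required = {"age_low", "age_high", "sex", "rate_per_100k"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"incidence table needs columns {sorted(required)}")
        if (self.table["rate_per_100k"] < 0).any():
            raise ValueError("incidence rates must be >= 0")
        for sex, grp in self.table.groupby("sex"):
            g = grp.sort_values("age_low")
            if not (g["age_high"].to_numpy()[:-1] == g["age_low"].to_numpy()[1:]).all():
                raise ValueError(f"age bands for {sex} not contiguous")

    def hazard(self, age: float, sex: str) -> float:
        """Annual incidence at ``age`` as a hazard (per person-year)."""
        g = self.table[self.table["sex"] == sex]
        row = g[(g["age_low"] <= age) & (age < g["age_high"])]
        if row.empty:
            raise ValueError(f"age {age} not covered by incidence table for {sex}")
        return float(row["rate_per_100k"].iloc[0]) / 100_000.0

    @classmethod
    def from_csv(cls, path) -> "IncidenceTable":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def default_incidence() -> IncidenceTable:
    """Synthetic age/sex incidence table, rising steeply with age.

    Shaped like UK population rates for an illustrative configuration
    (5-year bands, 50–80, male rates higher); not a transcription of any
    registry table.
    """
    bands = [(50, 55), (55, 60), (60, 65), (65, 70), (70, 75), (75, 80)]
    male = [60.0, 120.0, 220.0, 360.0, 520.0, 650.0]
    rows = []
    for (lo, hi), rate in zip(bands, male):
        rows.append({"age_low": lo, "age_high": hi, "sex": "male",
                     "rate_per_100k": rate})
        rows.append({"age_low": lo, "age_high": hi, "sex": "female",
                     "rate_per_100k": 0.75 * rate})
    return IncidenceTable(pd.DataFrame(rows))


@dataclass(frozen=True)
class RiskScore:
    relative_risk: float
    absolute_risk_5yr: float
    eligible: bool

    def __post_init__(self) -> None:
        if self.relative_risk <= 0:
            raise ValueError("relative_risk must be > 0")
        if not 0.0 <= self.absolute_risk_5yr <= 1.0:
            raise ValueError("absolute_risk_5yr must be in [0, 1]")


def _profile_levels(profile: RiskFactorProfile) -> dict[str, str]:
    yn = {True: "yes", False: "no"}
    return {
        "smoking_duration_band": smoking_duration_band(profile.smoking_duration),
        "respiratory_disease": yn[profile.respiratory_disease],
        "asbestos_exposure": yn[profile.asbestos_exposure],
        "prior_malignancy": yn[profile.prior_malignancy],
        "family_history": profile.family_history,
    }


def linear_predictor(profile: RiskFactorProfile, coeffs: LLPCoefficients) -> float:
    """Log-odds: intercept plus the matched coefficient of each factor level."""
    lp = coeffs.intercept
    for factor, level in _profile_levels(profile).items():
        lp += coeffs.lookup(factor, level)
    return lp


def absolute_risk_5yr(
    profile: RiskFactorProfile,
    coeffs: LLPCoefficients,
    incidence: IncidenceTable,
    mean_rr: float = 1.0,
) -> float:
    """5-year absolute risk from scaled age/sex incidence.

    ``mean_rr`` is the population-average relative risk; dividing by it
    keeps the scaled hazards consistent with the incidence table when
    averaged over the population the coefficients were fitted to.
    """
    if mean_rr <= 0:
        raise ValueError("mean_rr must be > 0")
    rr = math.exp(linear_predictor(profile, coeffs) - coeffs.intercept)
    cum = 0.0
    for t in range(5):
        cum += incidence.hazard(profile.age + t, profile.sex) * rr / mean_rr
    return 1.0 - math.exp(-cum)


def eligibility_gate(risk: float, threshold: float = ELIGIBILITY_THRESHOLD) -> bool:
    """True iff the 5-year absolute risk meets the gate (inclusive at 5%)."""
    if not 0.0 <= risk <= 1.0:
        raise ValueError("risk must be in [0, 1]")
    return risk >= threshold


def score_profiles(
    profiles,
    coeffs: LLPCoefficients,
    incidence: IncidenceTable,
    mean_rr: float = 1.0,
    threshold: float = ELIGIBILITY_THRESHOLD,
) -> pd.DataFrame:
    """Score an iterable of profiles; returns one row per profile.

    Columns: ``relative_risk``, ``absolute_risk_5yr``, ``eligible``.
    """
    if mean_rr <= 0:
        raise ValueError("mean_rr must be > 0")
    hazard_cache: dict[tuple[str, int], float] = {}

    def cum_hazard(age: int, sex: str) -> float:
        total = 0.0
        for t in range(5):
            key = (sex, age + t)
            if key not in hazard_cache:
                hazard_cache[key] = incidence.hazard(age + t, sex)
            total += hazard_cache[key]
        return total

    rows = []
    for p in profiles:
        rr = math.exp(linear_predictor(p, coeffs) - coeffs.intercept)
        ar = 1.0 - math.exp(-cum_hazard(p.age, p.sex) * rr / mean_rr)
        rows.append(
            {"relative_risk": rr, "absolute_risk_5yr": ar,
             "eligible": eligibility_gate(ar, threshold)}
        )
    return pd.DataFrame(rows)
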