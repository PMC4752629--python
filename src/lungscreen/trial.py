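"""Recruitment funnel, randomisation and trial outcome statistics.

The recruitment funnel mirrors a population-based screening trial:
questionnaires are mailed to a large population, positive responders are
risk-gated (5-year absolute risk >= 5%), gate passers return a second
questionnaire, and consenters are recruited up to a cap, then randomised
1:1 to screen and control arms.

Outcome statistics follow the pilot trial's bespoke definitions:

* false-positive rate    = (MDT referrals - confirmed cancers) / screened —
  subjects sent for diagnostic workup who did not have cancer;
* interval-imaging rate  = (category-3 subjects - category-3 cancers) / screened —
  subjects recalled solely for an early repeat CT, reported separately
  because the burden of a repeat scan differs from an MDT referral;
* benign resection rate  = benign surgeries / all surgical resections.

Rates are kept as raw fractions internally and rounded to one decimal
place of a percentage only for reporting.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .cohort import Participant

__all__ = [
    "FlowCounts",
    "SubjectRecord",
    "OutcomeStats",
    "apply_funnel",
    "randomise",
    "compute_outcome_stats",
    "compliance_ci_halfwidth",
    "UNDEFINED",
]

#: Undefined-marker for rates with a zero denominator.
UNDEFINED = math.nan

SURGERY_TREATMENTS = ("surgery", "surgery+chemo", "surgery+radio")
TREATMENTS = SURGERY_TREATMENTS + ("chemo", "radio", "chemo+radio", "palliative", "other")
DETECTION_ROUNDS = ("baseline", "3m", "12m")
STAGE_I = ("IA", "IB")
STAGE_II = ("IIA", "IIB")


@dataclass(frozen=True)
class FlowCounts:
    """Participant flow from first mailing to CT scan."""

    approached: int
    positive_responders: int
    negative_responders: int
    non_responders: int
    high_risk: int
    second_questionnaire_returned: int
    excluded: int
    randomised_total: int
    screen_arm: int
    control_arm: int
    scanned: int

    def __post_init__(self) -> None:
        if (self.positive_responders + self.negative_responders
                + self.non_responders != self.approached):
            raise ValueError("responder counts must sum to approached")
        if self.screen_arm + self.control_arm != self.randomised_total:
            raise ValueError("arms must sum to randomised_total")
        if self.scanned > self.screen_arm:
            raise ValueError("scanned cannot exceed screen arm")
        seq = (self.approached, self.positive_responders, self.high_risk,
               self.second_questionnaire_returned, self.randomised_total)
        if any(b > a for a, b in zip(seq, seq[1:])):
            raise ValueError("funnel stages must be non-increasing")


@dataclass
class SubjectRecord:
    """Per-subject screening outcome used by the statistics layer."""

    subject_id: str
    baseline_category: int
    referred_mdt: bool = False
    cancer_confirmed: bool = False
    detection_round: str | None = None  # baseline | 3m | 12m
    stage: str | None = None
    treatment: str | None = None
    surgery_performed: bool = False
    benign_surgery: bool = False
    had_followup_ct: bool = False

    def __post_init__(self) -> None:
        if self.baseline_category not in (1, 2, 3, 4):
            raise ValueError("baseline_category must be 1..4")
        if self.cancer_confirmed and self.stage is None:
            raise ValueError("confirmed cancer requires a stage")
        if self.cancer_confirmed and self.detection_round not in DETECTION_ROUNDS:
            raise ValueError("confirmed cancer requires a detection round")
        if self.benign_surgery and (self.cancer_confirmed or not self.surgery_performed):
            raise ValueError("benign_surgery implies surgery without cancer")
        if self.treatment is not None and self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")


@dataclass(frozen=True)
class OutcomeStats:
    """The trial's printed rates, as raw fractions (NaN where undefined)."""

    detection_rate: float
    baseline_prevalence: float
    mdt_referral_rate: float
    false_positive_rate: float
    interval_imaging_rate: float
    stage_I_fraction: float
    stage_I_II_fraction: float
    surgical_resection_fraction: float
    benign_resection_rate: float
    further_ct_fraction: float
    cat2_cancer_yield: float
    cat4_cancer_yield: float

    def as_percentages(self, ndigits: int = 1) -> dict[str, float]:
        """All rates as percentages rounded to ``ndigits`` decimal places."""
        return {
            k: (round(100.0 * v, ndigits) if not math.isnan(v) else UNDEFINED)
            for k, v in asdict(self).items()
        }


def apply_funnel(
    population: list[Participant],
    risk_scores: np.ndarray,
    rng: np.random.Generator,
    response_probs: tuple[float, float] = (0.307, 0.092),
    risk_threshold: float = 0.05,
    second_questionnaire_prob: float = 0.684,
    consent_prob: float = 0.681,
    cap: int | None = None,
) -> tuple[dict, list[Participant]]:
    """Thin a mailed population stage by stage down to recruited subjects.

    ``response_probs`` are (positive, negative) response probabilities; the
    remainder never reply.  Positive responders pass the risk gate when
    their absolute 5-year risk (aligned ``risk_scores``) meets
    ``risk_threshold``; gate passers return the second questionnaire, then
    consent, each as independent Bernoulli stages; recruitment stops at
    ``cap``.  Returns stage counts (pre-randomisation) and the recruited
    subjects.
    """
    p_pos, p_neg = response_probs
    if not (0 <= p_pos <= 1 and 0 <= p_neg <= 1 and p_pos + p_neg <= 1):
        raise ValueError("response probabilities invalid")
    n = len(population)
    if len(risk_scores) != n:
        raise ValueError("risk_scores must align with population")
    u = rng.random(n)
    positive = u < p_pos
    negative = (u >= p_pos) & (u < p_pos + p_neg)
    high_risk = positive & (np.asarray(risk_scores) >= risk_threshold)
    returned = high_risk & (rng.random(n) < second_questionnaire_prob)
    consented = returned & (rng.random(n) < consent_prob)

    recruited: list[Participant] = []
    idx = np.flatnonzero(consented)
    if cap is not None:
        idx = idx[: max(cap, 0)]
    for i in idx:
        recruited.append(population[i])
    counts = {
        "approached": n,
        "positive_responders": int(positive.sum()),
        "negative_responders": int(negative.sum()),
        "non_responders": int(n - positive.sum() - negative.sum()),
        "high_risk": int(high_risk.sum()),
        "second_questionnaire_returned": int(returned.sum()),
        "excluded": int(consented.sum() - len(recruited)),
        "recruited": len(recruited),
    }
    return counts, recruited


def randomise(
    recruited: list[Participant], rng: np.random.Generator
) -> tuple[list[Participant], list[Participant]]:
    """1:1 allocation by pseudo-random permutation; arm sizes differ by <= 1.

    With an odd count the screen arm receives the extra subject.  Sets each
    participant's ``arm`` attribute and returns (screen, control).
    """
    if not recruited:
        raise ValueError("nothing to randomise")
    order = rng.permutation(len(recruited))
    n_screen = (len(recruited) + 1) // 2
    screen, control = [], []
    for rank, i in enumerate(order):
        part = recruited[i]
        if rank < n_screen:
            part.arm = "screen"
            screen.append(part)
        else:
            part.arm = "control"
            control.append(part)
    return screen, control


def _frac(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def compute_outcome_stats(records: list[SubjectRecord], n_screened: int) -> OutcomeStats:
    """Compute the trial's outcome rates from per-subject records.

    ``n_screened`` is the number of subjects with a baseline scan (the
    denominator of the population-level rates); ``records`` may omit
    unremarkable category-1 subjects as long as ``n_screened`` counts them.
    """
    if n_screened < len({r.subject_id for r in records if r.referred_mdt}):
        raise ValueError("n_screened smaller than referred subjects")
    cancers = [r for r in records if r.cancer_confirmed]
    n_cancer = len(cancers)
    n_mdt = sum(r.referred_mdt for r in records)
    n_baseline = sum(
        r.detection_round in ("baseline", "3m") for r in cancers
    )
    cat3 = [r for r in records if r.baseline_category == 3]
    cat3_cancers = sum(r.cancer_confirmed for r in cat3)
    cat2 = [r for r in records if r.baseline_category == 2]
    cat4 = [r for r in records if r.baseline_category == 4]
    cancer_surgeries = sum(r.surgery_performed for r in cancers)
    benign_surgeries = sum(r.benign_surgery for r in records)
    n_stage_I = sum(r.stage in STAGE_I for r in cancers)
    n_stage_II = sum(r.stage in STAGE_II for r in cancers)
    return OutcomeStats(
        detection_rate=_frac(n_cancer, n_screened),
        baseline_prevalence=_frac(n_baseline, n_screened),
        mdt_referral_rate=_frac(n_mdt, n_screened),
        false_positive_rate=_frac(n_mdt - n_cancer, n_screened),
        interval_imaging_rate=_frac(len(cat3) - cat3_cancers, n_screened),
        stage_I_fraction=_frac(n_stage_I, n_cancer),
        stage_I_II_fraction=_frac(n_stage_I + n_stage_II, n_cancer),
        surgical_resection_fraction=_frac(cancer_surgeries, n_cancer),
        benign_resection_rate=_frac(
            benign_surgeries, cancer_surgeries + benign_surgeries
        ),
        further_ct_fraction=_frac(
            sum(r.had_followup_ct for r in records), n_screened
        ),
        cat2_cancer_yield=_frac(sum(r.cancer_confirmed for r in cat2), len(cat2)),
        cat4_cancer_yield=_frac(sum(r.cancer_confirmed for r in cat4), len(cat4)),
    )


def compliance_ci_halfwidth(p: float, n: int, level: float = 0.95) -> float:
    """Normal-approximation CI half-width for a proportion: z * sqrt(p(1-p)/n).

    Used at design time to check that an expected compliance proportion
    (e.g. 80% of ~2000 scanned subjects) is estimated to within the target
    precision (+-2 percentage points at 95% confidence).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(z * math.sqrt(p * (1.0 - p) / n))
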