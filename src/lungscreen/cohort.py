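"""Seeded synthetic screening-cohort generator.

Generates populations of high-risk individuals with the risk-factor
structure of a UK LDCT screening pilot cohort (heavy smoking history,
asbestos exposure, respiratory disease, prior malignancy, family history),
attaches ground-truth pulmonary nodules whose size distribution is
calibrated so that the downstream management pathway reproduces the
pilot's per-subject category proportions (~49/24/24/3% for categories
1–4), and simulates serial volumetric CT observations under exponential
nodule growth with multiplicative measurement noise.

Ground truth is explicit: each nodule carries a malignancy flag, a true
volume doubling time (VDT; +inf for static nodules) and, if malignant, a
stage at diagnosis.  Cancer prevalence among screened subjects defaults to
~2.1%.

All randomness flows from a single master seed through named
``numpy.random.SeedSequence`` child streams, so each generation stage is
independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .pathway import NoduleMeasurement, sphere_diameter

__all__ = [
    "RiskFactorProfile",
    "NoduleTruth",
    "Participant",
    "SynthConfig",
    "generate_population",
    "sow_nodules",
    "observe",
    "STATIC",
]

#: Sentinel VDT for nodules that do not grow.
STATIC = math.inf

SEXES = ("male", "female")
SMOKING_STATUSES = ("never", "current", "ex")
FAMILY_HISTORY_LEVELS = ("none", "early", "late")
STAGES = ("IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IV")


@dataclass(frozen=True)
class RiskFactorProfile:
    """Risk-factor profile of one individual aged 50–75."""

    age: int
    sex: str
    smoking_status: str
    smoking_duration: int  # years; 0 iff never smoker
    asbestos_exposure: bool
    respiratory_disease: bool  # COPD/emphysema/bronchitis/pneumonia/TB
    prior_malignancy: bool
    family_history: str  # none | early (<60 y) | late (>=60 y)

    def __post_init__(self) -> None:
        if not 50 <= self.age <= 75:
            raise ValueError(f"age {self.age} outside [50, 75]")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.smoking_status not in SMOKING_STATUSES:
            raise ValueError(f"unknown smoking_status {self.smoking_status!r}")
        if (self.smoking_duration == 0) != (self.smoking_status == "never"):
            raise ValueError("smoking_duration must be 0 iff never smoker")
        if self.smoking_duration < 0:
            raise ValueError("smoking_duration must be >= 0")
        if self.family_history not in FAMILY_HISTORY_LEVELS:
            raise ValueError(f"unknown family_history {self.family_history!r}")


@dataclass(frozen=True)
class NoduleTruth:
    """Ground truth of one simulated nodule."""

    baseline_volume: float  # mm^3
    malignant: bool
    true_vdt: float  # days; STATIC (+inf) for non-growing
    stage_if_cancer: str | None = None

    def __post_init__(self) -> None:
        if self.baseline_volume <= 0:
            raise ValueError("baseline_volume must be > 0")
        if self.true_vdt <= 0:
            raise ValueError("true_vdt must be > 0 days (or +inf)")
        if self.malignant and self.stage_if_cancer not in STAGES:
            raise ValueError("malignant nodule requires a stage")
        if not self.malignant and self.stage_if_cancer is not None:
            raise ValueError("benign nodule must have stage None")


@dataclass
class Participant:
    id: str
    profile: RiskFactorProfile
    nodules: list[NoduleTruth] = field(default_factory=list)
    arm: str = "unassigned"  # screen | control | unassigned


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration.

    Defaults reproduce the screened pilot cohort: risk-factor marginals of
    the randomised high-risk arm; a log-normal largest-nodule volume
    distribution quantile-matched to the per-subject category proportions
    979/479/472/64 over 1994; a logistic malignancy-vs-volume model matched
    to the category-3 and category-4 cancer yields (9/472, 32/64); log-normal
    VDT for malignant nodules (median 180 d) and a mostly static benign
    population with a slow-growing tail.
    """

    n_individuals: int = 2000
    seed: int = 0

    # --- risk-factor marginals (screened-arm anchors) ---
    male_fraction: float = 0.754
    age_mean: float = 67.1
    age_sd: float = 4.1
    smoking_status_probs: tuple[float, float, float] = (0.001, 0.383, 0.616)
    # duration bands for ever-smokers: (1-9, 10-19, 20+) years
    duration_band_probs: tuple[float, float, float] = (0.007, 0.058, 0.935)
    asbestos_prob: float = 0.376
    respiratory_prob: float = 0.521
    prior_malignancy_prob: float = 0.199
    family_history_probs: tuple[float, float, float] = (0.754, 0.106, 0.140)

    # --- nodule structure ---
    p_no_nodule: float = 0.30  # no nodule at all
    p_subthreshold: float = 0.191  # largest nodule <= 15 mm^3 (recorded as none)
    extra_nodule_rate: float = 0.0  # Poisson mean of additional smaller nodules
    # largest-recordable-nodule ln-volume (calibrated; see lungscreen.calibrate)
    volume_mu: float = 2.8051035340733868
    volume_sigma: float = 1.8524467398454514
    # P(malignant | V) = expit(a + b ln V) (calibrated)
    malignancy_intercept: float = -16.716496106385996
    malignancy_slope: float = 2.4352448337020163
    # VDT distributions (days)
    vdt_malignant_median: float = 180.0
    vdt_malignant_sigma: float = 0.7
    benign_growth_fraction: float = 0.12
    vdt_benign_median: float = 550.0
    vdt_benign_sigma: float = 0.5
    # stage-at-diagnosis distribution (IA, IB, IIA, IIB, IIIA, IIIB, IV),
    # frequencies of the pilot's 42 screen-detected cancers
    stage_probs: tuple[float, ...] = (
        26 / 42, 2 / 42, 7 / 42, 1 / 42, 3 / 42, 0.0, 3 / 42,
    )
    # volumetric measurement noise (coefficient of variation)
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be >= 0")
        for name in (
            "male_fraction", "asbestos_prob", "respiratory_prob",
            "prior_malignancy_prob", "p_no_nodule", "p_subthreshold",
            "benign_growth_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("smoking_status_probs", "duration_band_probs",
                     "family_history_probs", "stage_probs"):
            p = getattr(self, name)
            if any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        if self.p_no_nodule + self.p_subthreshold > 1.0:
            raise ValueError("p_no_nodule + p_subthreshold must be <= 1")
        if self.volume_sigma <= 0:
            raise ValueError("volume_sigma must be > 0")
        for name in ("vdt_malignant_median", "vdt_malignant_sigma",
                     "vdt_benign_median", "vdt_benign_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be > 0")


def _streams(config: SynthConfig) -> dict[str, np.random.Generator]:
    """One independent RNG stream per generation stage, from the master seed."""
    root = np.random.SeedSequence(config.seed)
    names = ("profiles", "nodules", "observe")
    return {
        name: np.random.Generator(np.random.PCG64(child))
        for name, child in zip(names, root.spawn(len(names)))
    }


def generate_population(config: SynthConfig) -> list[Participant]:
    """Draw ``config.n_individuals`` participants with independent risk factors.

    Factors are sampled from the configured marginals (ages from a normal
    clipped to [50, 75] and rounded to whole years).  Deterministic for a
    fixed config: the same seed yields byte-identical populations.
    """
    n = config.n_individuals
    rng = _streams(config)["profiles"]
    if n == 0:
        return []

    age = np.clip(np.rint(rng.normal(config.age_mean, config.age_sd, n)), 50, 75)
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    status = rng.choice(SMOKING_STATUSES, size=n, p=config.smoking_status_probs)
    band = rng.choice(3, size=n, p=config.duration_band_probs)
    dur_lo = np.array([1, 10, 20])[band]
    dur_hi = np.array([9, 19, 50])[band]
    duration = rng.integers(dur_lo, dur_hi + 1)
    duration = np.where(status == "never", 0, duration)
    asb = rng.random(n) < config.asbestos_prob
    resp = rng.random(n) < config.respiratory_prob
    prior = rng.random(n) < config.prior_malignancy_prob
    fh = rng.choice(FAMILY_HISTORY_LEVELS, size=n, p=config.family_history_probs)

    width = len(str(max(n - 1, 1)))
    return [
        Participant(
            id=f"S{i:0{width}d}",
            profile=RiskFactorProfile(
                age=int(age[i]),
                sex=str(sex[i]),
                smoking_status=str(status[i]),
                smoking_duration=int(duration[i]),
                asbestos_exposure=bool(asb[i]),
                respiratory_disease=bool(resp[i]),
                prior_malignancy=bool(prior[i]),
                family_history=str(fh[i]),
            ),
        )
        for i in range(n)
    ]


def _draw_vdt(rng: np.random.Generator, malignant: bool, config: SynthConfig) -> float:
    if malignant:
        return float(
            rng.lognormal(math.log(config.vdt_malignant_median),
                          config.vdt_malignant_sigma)
        )
    if rng.random() < config.benign_growth_fraction:
        return float(
            rng.lognormal(math.log(config.vdt_benign_median),
                          config.vdt_benign_sigma)
        )
    return STATIC


def sow_nodules(participants: list[Participant], config: SynthConfig) -> list[Participant]:
    """Attach ground-truth nodules to a generated population (in place).

    Each subject is nodule-free with probability ``p_no_nodule``, carries
    only sub-threshold (<= 15 mm^3) nodules with probability
    ``p_subthreshold``, and otherwise has a largest recordable nodule drawn
    from the calibrated truncated log-normal, plus ``Poisson(extra_nodule_rate)``
    additional smaller nodules.  Malignancy is Bernoulli in the calibrated
    logistic of ln-volume; malignant nodules receive a stage and a finite
    VDT, benign nodules are static apart from a slow-growing fraction.
    """
    from scipy.special import expit
    from scipy.stats import norm

    rng = _streams(config)["nodules"]
    ln15 = math.log(15.0)
    # truncated sampling bounds on the underlying normal CDF
    z_lo_rec = norm.cdf((ln15 - config.volume_mu) / config.volume_sigma)

    for part in participants:
        part.nodules = []
        u = rng.random()
        if u < config.p_no_nodule:
            continue
        volumes: list[float]
        if u < config.p_no_nodule + config.p_subthreshold:
            # sub-threshold largest nodule, truncated to (0, 15]
            q = rng.uniform(0.0, z_lo_rec)
            volumes = [math.exp(config.volume_mu
                                + config.volume_sigma * norm.ppf(q))]
        else:
            q = rng.uniform(z_lo_rec, 1.0)
            vmax = math.exp(config.volume_mu + config.volume_sigma * norm.ppf(q))
            volumes = [vmax]
            for _ in range(rng.poisson(config.extra_nodule_rate)):
                # additional nodules are no larger than the subject's largest
                qe = rng.uniform(0.0, q)
                volumes.append(
                    math.exp(config.volume_mu
                             + config.volume_sigma * norm.ppf(qe))
                )
        for v in volumes:
            p_mal = float(expit(config.malignancy_intercept
                                + config.malignancy_slope * math.log(v)))
            malignant = bool(rng.random() < p_mal)
            stage = None
            if malignant:
                stage = str(rng.choice(STAGES, p=config.stage_probs))
            part.nodules.append(
                NoduleTruth(
                    baseline_volume=float(v),
                    malignant=malignant,
                    true_vdt=_draw_vdt(rng, malignant, config),
                    stage_if_cancer=stage,
                )
            )
    return participants


def observe(
    nodule: NoduleTruth,
    timepoint: float,
    noise_cv: float,
    rng: np.random.Generator,
    subject_id: str = "S0",
    nodule_id: str = "n0",
) -> NoduleMeasurement:
    """Simulate a volumetric CT measurement of a nodule at ``timepoint`` days.

    The true volume follows exponential growth,
    ``V(t) = V0 * 2**(t / VDT)`` (static nodules keep V0).  Measurement
    error is multiplicative log-normal with coefficient of variation
    ``noise_cv``, scaled to be mean-preserving, so the expected measured
    volume equals the true volume.  The reported diameter is the
    sphere-equivalent diameter of the measured volume.
    """
    if timepoint < 0:
        raise ValueError("timepoint must be >= 0 days")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if math.isinf(nodule.true_vdt):
        true_v = nodule.baseline_volume
    else:
        true_v = nodule.baseline_volume * 2.0 ** (timepoint / nodule.true_vdt)
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        v = true_v * math.exp(rng.normal(-0.5 * sigma**2, sigma))
    else:
        v = true_v
    return NoduleMeasurement(
        subject_id=subject_id,
        nodule_id=nodule_id,
        timepoint=float(timepoint),
        volume=float(v),
        max_diameter=float(sphere_diameter(v)),
        volumetry_possible=True,
    )
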