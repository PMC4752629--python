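"""End-to-end trial simulation.

``simulate_screen_round`` takes a cohort of participants with ground-truth
nodules through a full screening round: baseline volumetric CT, category
assignment, scheduled follow-up scans, VDT growth assessment and MDT
referral, then converts the decision traces and ground truth into
per-subject outcome records.  MDT workup is modelled as perfectly
discriminating: a referred subject's cancer status equals their ground
truth, and a small fraction of benign referrals undergo surgery.

``run_end_to_end`` wires the whole trial together: synthetic population →
risk scoring and the 5% gate → recruitment funnel → 1:1 randomisation →
screening of the compliant screen arm → outcome statistics →
cost-effectiveness, all reproducible from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import econ, risk, trial
from .cohort import Participant, SynthConfig, generate_population, observe, sow_nodules
from .config import RunConfig
from .pathway import (
    CareDecision,
    NoduleMeasurement,
    PathwayThresholds,
    run_pathway,
    schedule,
    subject_category,
)

__all__ = ["ScreenRoundResult", "simulate_screen_round", "run_end_to_end"]

# empirical treatment mix of the pilot's screen-detected cancers, by stage group
TREATMENT_PROBS = {
    "I/II": (("surgery", 33 / 36), ("radio", 2 / 36), ("palliative", 1 / 36)),
    "III": (("surgery", 1 / 3), ("surgery+chemo", 1 / 3), ("chemo", 1 / 3)),
    "IV": (("chemo+radio", 1 / 3), ("palliative", 1 / 3), ("other", 1 / 3)),
}
#: benign surgery probability among benign MDT referrals (4 of 72 in the pilot)
P_BENIGN_SURGERY = 4 / 72

_ROUND_OF_TIME = {0.0: "baseline", 91.0: "3m", 365.0: "12m"}


@dataclass
class ScreenRoundResult:
    records: list[trial.SubjectRecord]
    stats: trial.OutcomeStats
    decisions: list[CareDecision]
    category_counts: dict[int, int]
    n_screened: int

    @property
    def category_proportions(self) -> dict[int, float]:
        n = max(self.n_screened, 1)
        return {k: v / n for k, v in sorted(self.category_counts.items())}


def _draw_treatment(stage: str, rng: np.random.Generator) -> str:
    if stage in ("IA", "IB", "IIA", "IIB"):
        group = "I/II"
    elif stage in ("IIIA", "IIIB"):
        group = "III"
    else:
        group = "IV"
    options, probs = zip(*TREATMENT_PROBS[group])
    return str(rng.choice(options, p=list(probs)))


def _detection_round(t: float, th: PathwayThresholds) -> str:
    if t == 0:
        return "baseline"
    if t <= th.followup_3m:
        return "3m"
    return "12m"


def simulate_screen_round(
    participants: list[Participant],
    config: SynthConfig,
    th: PathwayThresholds | None = None,
) -> ScreenRoundResult:
    """Screen a cohort (with nodules already sown) through one full round.

    Baseline measurements below the recording threshold (15 mm^3) are not
    recorded; growing nodules that cross it at a follow-up enter the trace
    as new nodules.  Returns per-subject records, outcome statistics and
    the full decision trace.  Deterministic given the cohort and config
    seed.
    """
    th = th or PathwayThresholds()
    root = np.random.SeedSequence(entropy=config.seed, spawn_key=(101,))
    rng_obs, rng_clin = (
        np.random.Generator(np.random.PCG64(s)) for s in root.spawn(2)
    )

    records: list[trial.SubjectRecord] = []
    all_decisions: list[CareDecision] = []
    category_counts: dict[int, int] = {1: 0, 2: 0, 3: 0, 4: 0}

    for part in participants:
        baseline: list[NoduleMeasurement] = []
        per_nodule: dict[str, object] = {}
        for j, nod in enumerate(part.nodules):
            nid = f"n{j}"
            per_nodule[nid] = nod
            m = observe(nod, 0.0, config.noise_cv, rng_obs,
                        subject_id=part.id, nodule_id=nid)
            if m.volume > th.record_min_volume:
                baseline.append(m)

        cat = subject_category(baseline, th)
        category_counts[cat] += 1
        measurements = list(baseline)
        for t in schedule(cat, th):
            for nid, nod in per_nodule.items():
                m = observe(nod, t, config.noise_cv, rng_obs,
                            subject_id=part.id, nodule_id=nid)
                known = any(x.nodule_id == nid for x in baseline)
                if known or m.volume > th.record_min_volume:
                    measurements.append(m)

        if measurements:
            decisions = run_pathway(measurements, th)
        else:
            decisions = [CareDecision(part.id, 0.0, "discharge", "baseline_category")]
        all_decisions.extend(decisions)

        referral = next((d for d in decisions if d.action == "refer_MDT"), None)
        malignant = [n for n in part.nodules if n.malignant]
        cancer = referral is not None and bool(malignant)
        stage = malignant[0].stage_if_cancer if cancer else None
        treatment = _draw_treatment(stage, rng_clin) if cancer else None
        benign_surgery = bool(
            referral is not None and not cancer
            and rng_clin.random() < P_BENIGN_SURGERY
        )
        records.append(
            trial.SubjectRecord(
                subject_id=part.id,
                baseline_category=cat,
                referred_mdt=referral is not None,
                cancer_confirmed=cancer,
                detection_round=(
                    _detection_round(referral.timepoint, th) if cancer else None
                ),
                stage=stage,
                treatment=treatment,
                surgery_performed=bool(
                    (cancer and treatment.startswith("surgery")) or benign_surgery
                ),
                benign_surgery=benign_surgery,
                had_followup_ct=cat in (2, 3),
            )
        )

    stats = trial.compute_outcome_stats(records, len(participants))
    return ScreenRoundResult(
        records=records,
        stats=stats,
        decisions=all_decisions,
        category_counts=category_counts,
        n_screened=len(participants),
    )


def _per_person_samples(
    result: ScreenRoundResult,
    cost_pp: float,
    gain_per_cancer: float,
    screening_cost_share: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-person cost and QALY arrays for the bootstrap.

    The screening/workup component is spent on everyone; the net treatment
    component and the QALY gain attach to detected cancers, scaled so the
    means match the aggregate per-person figures.
    """
    n = result.n_screened
    cancers = np.array([r.cancer_confirmed for r in result.records], dtype=bool)
    n_cancer = int(cancers.sum())
    costs = np.full(n, cost_pp * screening_cost_share)
    qalys = np.zeros(n)
    if n_cancer:
        costs[cancers] += cost_pp * (1.0 - screening_cost_share) * n / n_cancer
        qalys[cancers] = gain_per_cancer
    return costs, qalys


def run_end_to_end(config: RunConfig) -> dict:
    """Run the full pipeline and return a nested run report.

    Report sections: ``meta`` (master seed, config hash), ``flow``
    (recruitment funnel counts), ``outcomes`` (rates as percentages),
    ``category_proportions`` and ``cost_effectiveness``.  Identical configs
    produce identical reports.
    """
    master = np.random.SeedSequence(config.master_seed)
    s_funnel, s_rand, s_boot = master.spawn(3)
    rng_funnel = np.random.Generator(np.random.PCG64(s_funnel))
    rng_rand = np.random.Generator(np.random.PCG64(s_rand))

    synth = config.synth_config()
    th = config.pathway_thresholds()
    population = generate_population(synth)

    report: dict = {
        "meta": {"master_seed": config.master_seed, "config_sha256": config.sha256()}
    }

    if not population:
        report.update(
            {"flow": {}, "outcomes": {}, "category_proportions": {},
             "cost_effectiveness": {}}
        )
        return report

    coeffs = risk.default_coefficients()
    incidence = risk.default_incidence()
    scores = risk.score_profiles(
        (p.profile for p in population), coeffs, incidence, mean_rr=config.mean_rr,
        threshold=config.risk_threshold,
    )
    flow, recruited = trial.apply_funnel(
        population,
        scores["absolute_risk_5yr"].to_numpy(),
        rng_funnel,
        response_probs=config.response_probs,
        risk_threshold=config.risk_threshold,
        second_questionnaire_prob=config.second_questionnaire_prob,
        consent_prob=config.consent_prob,
        cap=config.cap,
    )

    screen_arm: list[Participant] = []
    control_arm: list[Participant] = []
    if recruited:
        screen_arm, control_arm = trial.randomise(recruited, rng_rand)
    compliant = [
        p for p in screen_arm if rng_funnel.random() < config.compliance_prob
    ]
    flow.update(
        {
            "randomised_total": len(recruited),
            "screen_arm": len(screen_arm),
            "control_arm": len(control_arm),
            "scanned": len(compliant),
        }
    )
    report["flow"] = flow

    sow_nodules(compliant, synth)
    result = simulate_screen_round(compliant, synth, th)
    report["outcomes"] = result.stats.as_percentages()
    report["category_proportions"] = {
        str(k): v for k, v in result.category_proportions.items()
    }

    cost_cfg = config.cost_config()
    effect = config.effect_config()
    life = econ.make_synthetic_lifetable()
    cost_pp = econ.per_person_incremental_cost(cost_cfg)
    det = result.stats.detection_rate
    gain_pp = econ.qaly_gain_pp(effect, life, detection_rate=det)
    ce: dict = {
        "delta_cost_pp": cost_pp,
        "delta_qaly_pp": gain_pp,
        "icer": econ.icer(cost_pp, gain_pp),
        "currency": cost_cfg.currency_label,
    }
    if det > 0 and result.n_screened >= 2:
        gain_per_cancer = gain_pp / det
        screening_share = (
            (cost_cfg.screening_workup_cost_pp or 0.0) / cost_pp if cost_pp else 1.0
        )
        costs_i, qalys_i = _per_person_samples(
            result, cost_pp, gain_per_cancer, screening_share
        )
        lo, hi, _ = econ.bootstrap_ci(
            costs_i, qalys_i, n_bootstrap=config.n_bootstrap,
            seed=int(s_boot.generate_state(1)[0] % (2**31)),
        )
        ce.update({"ci_low": lo, "ci_high": hi, "n_bootstrap": config.n_bootstrap})
    report["cost_effectiveness"] = ce

    if config.output_dir is not None:
        _write_artifacts(config, report, compliant, result)
    return report


def _write_artifacts(config: RunConfig, report: dict,
                     compliant: list[Participant], result: ScreenRoundResult) -> None:
    from pathlib import Path

    from .io import decisions_to_csv, population_to_csv, write_json_report

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = report["meta"]
    population_to_csv(compliant, out / "screened_population.csv",
                      out / "screened_nodules.csv", meta=meta)
    decisions_to_csv(result.decisions, out / "care_decisions.csv", meta=meta)
    write_json_report(report, out / "report.json")
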