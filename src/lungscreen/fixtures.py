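"""Packaged reference fixtures.

Small transcriptions of the pilot trial's printed summary tables, shipped
as JSON/CSV package data:

* per-subject nodule-category counts with MDT referrals and cancers,
* the 42 screen-detected cancer case records (stage, histology, treatment),
* the recruitment funnel counts,
* the published cost-effectiveness figures,
* the cohort risk-factor marginals,
* the printed outcome rates used as expected values.

:func:`records_from_fixture` expands the summary counts plus the case
table into one :class:`~lungscreen.trial.SubjectRecord` per screened
subject, so the statistics layer can recompute every printed rate from
per-subject data rather than from the pre-aggregated numbers.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .trial import OutcomeStats, SubjectRecord, compute_outcome_stats

__all__ = [
    "load_category_counts",
    "load_cancer_cases",
    "load_funnel_counts",
    "load_econ_reference",
    "load_cohort_marginals",
    "load_reference_rates",
    "records_from_fixture",
    "evaluate_fixtures",
]

_DATA = resources.files("lungscreen") / "data"


def _read_json(name: str) -> dict:
    with (_DATA / name).open("r", encoding="utf-8") as fh:
        return json.load(fh)


def load_category_counts() -> dict:
    """Per-category subject/MDT/cancer counts (keys '1'..'4') plus totals."""
    return _read_json("nodule_categories.json")


def load_cancer_cases() -> pd.DataFrame:
    """The 42 screen-detected cancers: category, detection round, stage, treatment."""
    with (_DATA / "cancer_cases.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_funnel_counts() -> dict:
    return _read_json("recruitment_funnel.json")


def load_econ_reference() -> dict:
    return _read_json("economics_reference.json")


def load_cohort_marginals() -> dict:
    return _read_json("cohort_marginals.json")


def load_reference_rates() -> dict[str, float]:
    d = _read_json("reference_rates.json")
    d.pop("description", None)
    return d


def records_from_fixture() -> tuple[list[SubjectRecord], int]:
    """Expand the fixture tables into per-subject records.

    Cancer subjects come straight from the case table.  Non-cancer MDT
    referrals per category are filled in from the count differences; the
    four benign surgeries are assigned among them.  Remaining subjects are
    unreferred members of their category.  Returns (records, n_screened).
    """
    counts = load_category_counts()
    cases = load_cancer_cases()
    records: list[SubjectRecord] = []

    for _, row in cases.iterrows():
        treatment = str(row["treatment"])
        records.append(
            SubjectRecord(
                subject_id=f"case{int(row['case']):02d}",
                baseline_category=int(row["baseline_category"]),
                referred_mdt=True,
                cancer_confirmed=True,
                detection_round=str(row["detection_round"]),
                stage=str(row["stage"]),
                treatment=treatment,
                surgery_performed=treatment.startswith("surgery"),
                had_followup_ct=int(row["baseline_category"]) in (2, 3),
            )
        )

    benign_surgery_left = int(counts["benign_surgeries"])
    for cat_str, c in counts["categories"].items():
        cat = int(cat_str)
        n_cancer = int(c["cancers"])
        n_fp = int(c["mdt_referrals"]) - n_cancer
        n_rest = int(c["subjects"]) - int(c["mdt_referrals"])
        for i in range(n_fp):
            benign = benign_surgery_left > 0 and cat == 4
            if benign:
                benign_surgery_left -= 1
            records.append(
                SubjectRecord(
                    subject_id=f"fp{cat}_{i:03d}",
                    baseline_category=cat,
                    referred_mdt=True,
                    surgery_performed=benign,
                    benign_surgery=benign,
                    had_followup_ct=cat in (2, 3),
                )
            )
        for i in range(n_rest):
            records.append(
                SubjectRecord(
                    subject_id=f"s{cat}_{i:03d}",
                    baseline_category=cat,
                    had_followup_ct=cat in (2, 3),
                )
            )
    return records, int(counts["n_screened"])


def evaluate_fixtures() -> pd.DataFrame:
    """Recompute every printed outcome rate from the expanded fixture records.

    Returns a table with one row per rate: the recomputed percentage (one
    decimal place), the expected printed value, and whether they agree
    exactly.
    """
    records, n_screened = records_from_fixture()
    stats: OutcomeStats = compute_outcome_stats(records, n_screened)
    computed = stats.as_percentages()
    expected = load_reference_rates()
    rows = [
        {
            "rate": name,
            "computed_pct": computed[name],
            "expected_pct": exp,
            "match": computed[name] == exp,
        }
        for name, exp in expected.items()
    ]
    return pd.DataFrame(rows)
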