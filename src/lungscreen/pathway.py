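"""Volumetric nodule management pathway.

Implements the four-category classification of screen-detected pulmonary
nodules by volume (primary) or maximum diameter (fallback when volumetry is
not possible), the follow-up schedule attached to each category, volume
doubling time (VDT) growth assessment between serial CT scans, and the
resulting care decisions (discharge, repeat imaging, or referral to the
multidisciplinary team, MDT).

Category boundaries follow the "greater than" convention throughout: a
nodule must strictly exceed a cut-point to move up a category.

  category 1:  volume <= 15 mm^3   (diameter <= 3 mm)   -> no action
  category 2:  15 < V <= 50 mm^3   (3 < d <= 5 mm)      -> repeat CT at 12 months
  category 3:  50 < V <= 500 mm^3  (5 < d <= 10 mm)     -> repeat CT at 3 and 12 months
  category 4:  V > 500 mm^3        (d > 10 mm)          -> immediate MDT referral

On follow-up, any nodule whose pairwise VDT against its most recent prior
measurement is below 400 days is referred to the MDT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "NoduleMeasurement",
    "PathwayThresholds",
    "CareDecision",
    "NO_GROWTH",
    "categorize_nodule",
    "subject_category",
    "compute_vdt",
    "schedule",
    "run_pathway",
    "sphere_diameter",
    "sphere_volume",
]

#: Sentinel returned by :func:`compute_vdt` for stable or shrinking nodules.
NO_GROWTH = math.inf


def sphere_diameter(volume: float) -> float:
    """Sphere-equivalent diameter (mm) of a volume (mm^3): d = (6V/pi)^(1/3)."""
    if volume < 0:
        raise ValueError("volume must be non-negative")
    return (6.0 * volume / math.pi) ** (1.0 / 3.0)


def sphere_volume(diameter: float) -> float:
    """Volume (mm^3) of a sphere of the given diameter (mm)."""
    if diameter < 0:
        raise ValueError("diameter must be non-negative")
    return math.pi * diameter**3 / 6.0


@dataclass(frozen=True)
class NoduleMeasurement:
    """One volumetric (or diameter-only) observation of one nodule.

    ``volumetry_possible`` governs which size measure drives management:
    volume when true, maximum diameter otherwise. ``benign_features`` marks
    radiologically benign nodules (e.g. fully calcified), which are always
    category 1 regardless of size.
    """

    subject_id: str
    nodule_id: str
    timepoint: float  # days since baseline scan
    volume: float | None = None  # mm^3
    max_diameter: float | None = None  # mm
    volumetry_possible: bool = True
    benign_features: bool = False

    def __post_init__(self) -> None:
        if self.timepoint < 0:
            raise ValueError("timepoint must be >= 0 days")
        if self.volumetry_possible:
            if self.volume is None:
                raise ValueError("volumetry_possible requires a volume")
            if self.volume <= 0:
                raise ValueError("volume must be > 0 mm^3 when present")
        else:
            if self.max_diameter is None:
                raise ValueError(
                    "max_diameter required when volumetry is not possible"
                )
            if self.max_diameter <= 0:
                raise ValueError("max_diameter must be > 0 mm when present")


@dataclass(frozen=True)
class PathwayThresholds:
    """Size cut-points (mm^3 / mm), VDT referral threshold and follow-up times.

    Defaults encode the pilot-trial protocol: recording threshold 15 mm^3 or
    3 mm, category cuts at 50/500 mm^3 (5/10 mm), growth referral at
    VDT < 400 days, follow-up scans at 3 and 12 months (91/365 days by the
    declared months-to-days convention).
    """

    record_min_volume: float = 15.0
    record_min_diameter: float = 3.0
    cat2_max_volume: float = 50.0
    cat2_max_diameter: float = 5.0
    cat3_max_volume: float = 500.0
    cat3_max_diameter: float = 10.0
    vdt_referral: float = 400.0  # days
    followup_3m: float = 91.0  # days
    followup_12m: float = 365.0  # days

    def __post_init__(self) -> None:
        if not (self.record_min_volume < self.cat2_max_volume < self.cat3_max_volume):
            raise ValueError("volume cut-points must be strictly increasing")
        if not (
            self.record_min_diameter < self.cat2_max_diameter < self.cat3_max_diameter
        ):
            raise ValueError("diameter cut-points must be strictly increasing")
        if self.vdt_referral <= 0:
            raise ValueError("vdt_referral must be > 0 days")
        if not 0 < self.followup_3m < self.followup_12m:
            raise ValueError("follow-up times must be positive and ordered")


@dataclass(frozen=True)
class CareDecision:
    """A management decision for one subject at one timepoint."""

    subject_id: str
    timepoint: float
    action: str  # discharge | repeat_12m | repeat_3m_then_12m | refer_MDT
    reason: str  # baseline_category | growth_vdt | new_nodule
    note: str = ""

    _ACTIONS = ("discharge", "repeat_12m", "repeat_3m_then_12m", "refer_MDT")
    _REASONS = ("baseline_category", "growth_vdt", "new_nodule")

    def __post_init__(self) -> None:
        if self.action not in self._ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.reason not in self._REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if self.action == "refer_MDT" and self.reason == "growth_vdt" and self.timepoint <= 0:
            raise ValueError("growth referral cannot occur at baseline")


def categorize_nodule(m: NoduleMeasurement, th: PathwayThresholds | None = None) -> int:
    """Assign the four-level management category of a single nodule.

    Volume drives the decision whenever volumetry is possible; the maximum
    diameter is the fallback. All lower bounds are exclusive ("greater
    than"), so a nodule exactly at 15 mm^3 (3 mm) is category 1.
    """
    th = th or PathwayThresholds()
    if m.benign_features:
        return 1
    if m.volumetry_possible:
        v = m.volume
        assert v is not None
        if v <= th.record_min_volume:
            return 1
        if v <= th.cat2_max_volume:
            return 2
        if v <= th.cat3_max_volume:
            return 3
        return 4
    d = m.max_diameter
    assert d is not None
    if d <= th.record_min_diameter:
        return 1
    if d <= th.cat2_max_diameter:
        return 2
    if d <= th.cat3_max_diameter:
        return 3
    return 4


def subject_category(
    measurements: Sequence[NoduleMeasurement], th: PathwayThresholds | None = None
) -> int:
    """Subject-level category at one timepoint: the maximum over nodules.

    A subject with no recorded nodules is category 1.  All measurements must
    belong to the same subject.
    """
    if not measurements:
        return 1
    subjects = {m.subject_id for m in measurements}
    if len(subjects) > 1:
        raise ValueError(f"measurements mix subjects: {sorted(subjects)}")
    return max(categorize_nodule(m, th) for m in measurements)


def compute_vdt(v1: float, v2: float, delta_t: float) -> float:
    """Volume doubling time in days under exponential growth.

    VDT = delta_t * ln 2 / ln(v2/v1).  Stable or shrinking nodules
    (v2 <= v1) return the :data:`NO_GROWTH` sentinel (+inf) — they never
    trigger a growth referral.
    """
    if v1 <= 0 or v2 <= 0:
        raise ValueError("volumes must be > 0")
    if delta_t <= 0:
        raise ValueError("delta_t must be > 0 days")
    if v2 <= v1:
        return NO_GROWTH
    return delta_t * math.log(2.0) / math.log(v2 / v1)


def schedule(category: int, th: PathwayThresholds | None = None) -> list[float]:
    """Follow-up CT timepoints (days) implied by a baseline category.

    Category 1 and 4 have no scheduled follow-up: 1 is discharged, 4 is
    referred to the MDT immediately.
    """
    th = th or PathwayThresholds()
    if category == 1:
        return []
    if category == 2:
        return [th.followup_12m]
    if category == 3:
        return [th.followup_3m, th.followup_12m]
    if category == 4:
        return []
    raise ValueError(f"invalid category {category}")


_BASELINE_ACTION = {
    1: "discharge",
    2: "repeat_12m",
    3: "repeat_3m_then_12m",
    4: "refer_MDT",
}


def run_pathway(
    measurements: Iterable[NoduleMeasurement],
    th: PathwayThresholds | None = None,
) -> list[CareDecision]:
    """Run the care pathway for one subject across all their scans.

    The baseline (day 0) scan sets the subject category and the follow-up
    schedule. At each scheduled follow-up with measurements, every nodule is
    assessed pairwise against its most recent prior measurement; any nodule
    growing with 0 < VDT < ``vdt_referral`` triggers an MDT referral (at
    most one per subject — the pathway stops there). Nodules first seen at a
    follow-up are categorized as at baseline; a new category-4 nodule is
    referred. Otherwise the schedule continues and the subject is discharged
    after the last scheduled scan.
    """
    th = th or PathwayThresholds()
    ms = sorted(measurements, key=lambda m: (m.timepoint, m.nodule_id))
    if not ms:
        raise ValueError("no measurements supplied")
    subjects = {m.subject_id for m in ms}
    if len(subjects) > 1:
        raise ValueError(f"measurements mix subjects: {sorted(subjects)}")
    sid = ms[0].subject_id

    by_time: dict[float, list[NoduleMeasurement]] = {}
    for m in ms:
        by_time.setdefault(m.timepoint, []).append(m)
    times = sorted(by_time)
    if times[0] != 0:
        raise ValueError(f"subject {sid}: baseline (day 0) scan missing")

    baseline = by_time[0.0] if 0.0 in by_time else by_time[times[0]]
    cat0 = subject_category(baseline, th)
    decisions = [
        CareDecision(sid, 0.0, _BASELINE_ACTION[cat0], "baseline_category")
    ]
    if cat0 in (1, 4):
        return decisions

    planned = schedule(cat0, th)
    last_seen: dict[str, NoduleMeasurement] = {m.nodule_id: m for m in baseline}

    for i, t in enumerate(planned):
        if t not in by_time:
            raise ValueError(
                f"subject {sid}: scheduled scan at day {t:g} has no measurements"
            )
        current = by_time[t]
        current_ids = {m.nodule_id for m in current}
        missing = set(last_seen) - current_ids
        if missing:
            raise ValueError(
                f"subject {sid}: nodules {sorted(missing)} unmatched at day {t:g}"
            )

        referral: CareDecision | None = None
        for m in current:
            prev = last_seen.get(m.nodule_id)
            if prev is None:
                # nodule first seen at follow-up: treated as at baseline
                if categorize_nodule(m, th) == 4 and referral is None:
                    referral = CareDecision(sid, t, "refer_MDT", "new_nodule")
                continue
            if not (m.volumetry_possible and prev.volumetry_possible):
                continue  # growth assessment requires volumetry at both scans
            vdt = compute_vdt(prev.volume, m.volume, t - prev.timepoint)
            if vdt < th.vdt_referral and referral is None:
                referral = CareDecision(
                    sid, t, "refer_MDT", "growth_vdt",
                    note=f"nodule {m.nodule_id} VDT {vdt:.0f} d",
                )
        for m in current:
            last_seen[m.nodule_id] = m

        if referral is not None:
            decisions.append(referral)
            return decisions

        if i < len(planned) - 1:
            decisions.append(CareDecision(sid, t, "repeat_12m", "baseline_category"))
        else:
            note = ""
            cat_now = subject_category(current, th)
            if cat_now > cat0:
                note = f"category increased {cat0}->{cat_now} without VDT<{th.vdt_referral:g}"
            decisions.append(
                CareDecision(sid, t, "discharge", "baseline_category", note=note)
            )
    return decisions
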