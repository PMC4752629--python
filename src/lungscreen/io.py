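"""CSV/JSON readers and writers for populations, measurements and decisions.

CSV dialect: UTF-8, comma-separated, header row, "." decimal.  Files
written by the pipeline carry a leading comment block declaring the master
seed and config hash (lines starting with ``#``); the readers here skip
such comments.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .cohort import NoduleTruth, Participant, RiskFactorProfile
from .pathway import CareDecision, NoduleMeasurement

__all__ = [
    "population_to_csv",
    "population_from_csv",
    "measurements_to_csv",
    "measurements_from_csv",
    "decisions_to_csv",
    "write_json_report",
]


def _write_with_meta(df: pd.DataFrame, path, meta: dict | None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, float_format=lambda x: repr(float(x)))


def population_to_csv(
    participants: list[Participant],
    participants_path,
    nodules_path=None,
    meta: dict | None = None,
) -> None:
    """One row per participant; a companion nodules CSV when requested."""
    rows = []
    for p in participants:
        row = {"id": p.id, "arm": p.arm}
        row.update(vars(p.profile))
        rows.append(row)
    _write_with_meta(pd.DataFrame(rows), participants_path, meta)

    if nodules_path is not None:
        nrows = []
        for p in participants:
            for j, nod in enumerate(p.nodules):
                nrows.append(
                    {
                        "participant_id": p.id,
                        "nodule_index": j,
                        "baseline_volume": nod.baseline_volume,
                        "malignant": nod.malignant,
                        "vdt": nod.true_vdt,
                        "stage": nod.stage_if_cancer or "",
                    }
                )
        _write_with_meta(pd.DataFrame(nrows), nodules_path, meta)


def population_from_csv(participants_path, nodules_path=None) -> list[Participant]:
    df = pd.read_csv(participants_path, comment="#", float_precision="round_trip")
    participants = []
    for _, r in df.iterrows():
        profile = RiskFactorProfile(
            age=int(r["age"]),
            sex=str(r["sex"]),
            smoking_status=str(r["smoking_status"]),
            smoking_duration=int(r["smoking_duration"]),
            asbestos_exposure=bool(r["asbestos_exposure"]),
            respiratory_disease=bool(r["respiratory_disease"]),
            prior_malignancy=bool(r["prior_malignancy"]),
            family_history=str(r["family_history"]),
        )
        participants.append(Participant(id=str(r["id"]), profile=profile,
                                        arm=str(r["arm"])))
    if nodules_path is not None:
        by_id = {p.id: p for p in participants}
        ndf = pd.read_csv(nodules_path, comment="#", float_precision="round_trip")
        for _, r in ndf.iterrows():
            stage = str(r["stage"]) if isinstance(r["stage"], str) and r["stage"] else None
            by_id[str(r["participant_id"])].nodules.append(
                NoduleTruth(
                    baseline_volume=float(r["baseline_volume"]),
                    malignant=bool(r["malignant"]),
                    true_vdt=float(r["vdt"]),
                    stage_if_cancer=stage,
                )
            )
    return participants


def measurements_to_csv(measurements: list[NoduleMeasurement], path,
                        meta: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "nodule_id": m.nodule_id,
                "timepoint": m.timepoint,
                "volume": "" if m.volume is None else m.volume,
                "max_diameter": "" if m.max_diameter is None else m.max_diameter,
                "volumetry_possible": m.volumetry_possible,
                "benign_features": m.benign_features,
            }
            for m in measurements
        ]
    )
    _write_with_meta(df, path, meta)


def measurements_from_csv(path) -> list[NoduleMeasurement]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    out = []
    for _, r in df.iterrows():
        vol = r.get("volume")
        dia = r.get("max_diameter")
        out.append(
            NoduleMeasurement(
                subject_id=str(r["subject_id"]),
                nodule_id=str(r["nodule_id"]),
                timepoint=float(r["timepoint"]),
                volume=None if pd.isna(vol) else float(vol),
                max_diameter=None if pd.isna(dia) else float(dia),
                volumetry_possible=bool(r.get("volumetry_possible", True)),
                benign_features=bool(r.get("benign_features", False)),
            )
        )
    return out


def decisions_to_csv(decisions: list[CareDecision], path,
                     meta: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": d.subject_id,
                "timepoint": d.timepoint,
                "action": d.action,
                "reason": d.reason,
                "note": d.note,
            }
            for d in decisions
        ]
    )
    _write_with_meta(df, path, meta)


def _json_default(o):
    if isinstance(o, float) and math.isnan(o):  # pragma: no cover
        return None
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_json_report(report: dict, path) -> None:
    """Write a report dict as JSON (NaN rendered as null)."""
    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, float) and math.isnan(x):
            return None
        return x

    Path(path).write_text(
        json.dumps(clean(report), indent=2, sort_keys=True), encoding="utf-8"
    )
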