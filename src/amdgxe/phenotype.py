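"""Case/control classification and eye-level record construction.

Disease status follows the Rotterdam staging of the worst eye: stages
2a-4 define a case; stage 0 qualifies as a control only above age 60 and
stage 1 only above age 70 (stricter age floors reduce the chance of
labelling a subject who may still progress as a control).  Everyone else
is excluded.

For analysis each retained subject is expanded into one record per
gradable eye (the analysis unit), the eye outcome being 1 when that eye's
own stage is in the case set.  Subject-level covariates (age category,
sex, smoking, exercise, dichotomized GRS and diet adherence) are shared
by both eyes; the subject id is the cluster id for the GEE.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CASE_STAGES, STAGE_MISSING

__all__ = [
    "AGE_CATEGORIES",
    "classify_subject",
    "age_category",
    "build_eye_records",
]

#: Analysis age bins (reference first).  The printed bins overlap at their
#: endpoints; here they are the disjoint half-open intervals [.,70),
#: [70,75), [75,inf).  Subjects younger than 60 (possible for cases, since
#: enrolment starts at 55) fall in the reference bin.
AGE_CATEGORIES: tuple[str, ...] = ("60-70", "70-75", ">75")

_STAGE_ORDER = {"0": 0, "1": 1, "2a": 2, "2b": 3, "3": 4, "4": 5}


def _worst_stage(stages: list[str]) -> str:
    graded = [s for s in stages if s != STAGE_MISSING]
    return max(graded, key=_STAGE_ORDER.__getitem__)


def classify_subject(stage_right: str, stage_left: str, age: float) -> str:
    """Classify one subject as ``"case"``, ``"control"`` or ``"excluded"``.

    The phenotype is determined by the most severe gradable eye.
    """
    worst = _worst_stage([stage_right, stage_left])
    if worst in CASE_STAGES:
        return "case"
    if worst == "0" and age > 60:
        return "control"
    if worst == "1" and age > 70:
        return "control"
    return "excluded"


def age_category(age: float) -> str:
    """Analysis age bin: [.,70) -> "60-70" (reference), [70,75) -> "70-75", else ">75"."""
    if age < 70:
        return AGE_CATEGORIES[0]
    if age < 75:
        return AGE_CATEGORIES[1]
    return AGE_CATEGORIES[2]


def build_eye_records(phenotypes: pd.DataFrame, grs_results: pd.DataFrame,
                      mediscores: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand retained subjects into per-eye analysis records.

    Returns ``(records, exclusions)``.  ``records`` has one row per
    gradable eye of every subject who (a) classifies as case or control,
    (b) has a valid, dichotomized GRS and (c) has a mediSCORE.  Subjects
    failing any requirement are dropped into ``exclusions`` with a reason,
    never raised on.
    """
    grs = grs_results.set_index("subject_id")
    diet = mediscores.set_index("subject_id")

    records, exclusions = [], []
    for _, sub in phenotypes.iterrows():
        sid = sub["subject_id"]
        status = classify_subject(sub["stage_right"], sub["stage_left"], sub["age"])
        if status == "excluded":
            exclusions.append({"subject_id": sid, "reason": "fails case/control definition"})
            continue
        if sid not in grs.index:
            exclusions.append({"subject_id": sid, "reason": "no GRS result"})
            continue
        if not grs.at[sid, "included"]:
            exclusions.append({"subject_id": sid, "reason": "GRS invalid (missing major variant)"})
            continue
        if sid not in diet.index:
            exclusions.append({"subject_id": sid, "reason": "no mediSCORE"})
            continue
        shared = {
            "subject_id": sid,
            "status": status,
            "age": float(sub["age"]),
            "age_cat": age_category(float(sub["age"])),
            "sex": sub["sex"],
            "smoking": sub["smoking"],
            "exercise": bool(sub["exercise"]),
            "high_grs": bool(grs.at[sid, "high_grs"]),
            "high_mediscore": bool(diet.at[sid, "high_adherence"]),
            "grs": float(grs.at[sid, "grs"]),
            "mediscore": int(diet.at[sid, "total"]),
        }
        for eye, stage in (("right", sub["stage_right"]), ("left", sub["stage_left"])):
            if stage == STAGE_MISSING:
                continue
            records.append({**shared, "eye": eye, "stage": stage,
                            "outcome": int(stage in CASE_STAGES)})
    rec_df = pd.DataFrame(records)
    exc_df = pd.DataFrame(exclusions, columns=["subject_id", "reason"])
    return rec_df, exc_df
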