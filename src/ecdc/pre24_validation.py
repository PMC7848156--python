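"""Clinical validation of the subgroups against pre-24-month care history.

Two external checks of the clustering (which only ever sees ages 24-60
months): first, each subgroup's medical and dental profile before 24 months
— cost, visit counts, chronic-disease complexity, early dental exposure —
should show non-random gradients if the clusters are clinically real;
second, the whole analysis re-run on the urban stratum should reproduce the
subgroup structure.

Medical complexity uses a three-level chronic-disease stratifier with the
decision skeleton of pediatric complexity algorithms: chronic diagnoses
spanning two or more body systems (or any progressive/malignant condition)
mark a patient complex-chronic; exactly one chronic body system marks
non-complex chronic; otherwise no chronic disease.  The ICD-prefix ->
body-system map is configuration (YAML), not a clinical code inventory.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd
import yaml

from .claims_io import age_months
from .clustering import LABEL_ORDER, SubgroupLabel


class ComplexityLevel(Enum):
    COMPLEX_CHRONIC = "complex_chronic"
    NONCOMPLEX_CHRONIC = "noncomplex_chronic"
    NO_CHRONIC = "no_chronic"


#: Default chronic-code map: ICD prefix -> {"system": ..., "progressive": bool}.
#: Deliberately small; real deployments supply their own YAML.
DEFAULT_CHRONIC_CODE_MAP = {
    "Q24": {"system": "cardiovascular", "progressive": False},
    "G80": {"system": "neurologic", "progressive": False},
    "J45": {"system": "respiratory", "progressive": False},
    "K21": {"system": "gastrointestinal", "progressive": False},
    "E10": {"system": "endocrine", "progressive": False},
    "D61": {"system": "hematologic", "progressive": True},
    "C91": {"system": "malignancy", "progressive": True},
}


def load_chronic_code_map(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_chronic_code_map(code_map: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(code_map, fh, sort_keys=True)


def classify_complexity(diagnosis_codes, chronic_code_map: dict = DEFAULT_CHRONIC_CODE_MAP) -> ComplexityLevel:
    """Three-level complexity of one patient from pooled diagnosis codes.

    COMPLEX_CHRONIC if chronic codes span >= 2 body systems or any matched
    prefix is flagged progressive/malignant; NONCOMPLEX_CHRONIC for exactly
    one body system without such a flag; NO_CHRONIC otherwise.  Codes are
    matched by undotted upper-case prefix.
    """
    if not chronic_code_map:
        raise ValueError("chronic_code_map must not be empty")
    systems: set[str] = set()
    progressive = False
    for code in diagnosis_codes:
        code = str(code).upper().replace(".", "")
        for prefix, info in chronic_code_map.items():
            if code.startswith(prefix):
                systems.add(info["system"])
                progressive = progressive or bool(info.get("progressive", False))
    if progressive or len(systems) >= 2:
        return ComplexityLevel.COMPLEX_CHRONIC
    if len(systems) == 1:
        return ComplexityLevel.NONCOMPLEX_CHRONIC
    return ComplexityLevel.NO_CHRONIC


def _split_dx(joined: str) -> list[str]:
    return [c for c in str(joined).split(";") if c]


def classify_cohort_complexity(claims: pd.DataFrame, patient_ids,
                               chronic_code_map: dict = DEFAULT_CHRONIC_CODE_MAP,
                               max_age_months: int = 24) -> pd.Series:
    """Complexity level per patient from diagnoses before *max_age_months*."""
    months = age_months(claims["service_age_days"])
    young = claims[(months < max_age_months) & (claims["diagnosis_codes"] != "")]
    pooled = young.groupby("patient_id")["diagnosis_codes"].apply(
        lambda s: [c for joined in s for c in _split_dx(joined)]
    )
    out = {}
    for pid in patient_ids:
        out[pid] = classify_complexity(pooled.get(pid, []), chronic_code_map)
    return pd.Series(out, name="complexity").rename_axis("patient_id")


def _median_iqr(values) -> tuple[float, float, float]:
    if len(values) == 0:
        return np.nan, np.nan, np.nan
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3)


def pre24_profile(claims: pd.DataFrame, patients: pd.DataFrame,
                  labels_by_patient: pd.Series,
                  chronic_code_map: dict = DEFAULT_CHRONIC_CODE_MAP) -> pd.DataFrame:
    """Per-subgroup medical/dental profile at ages [0, 24) months.

    One row per subgroup plus an ``Overall`` row pooled over all patients
    (not the mean of the subgroup rows).  Columns: median/q1/q3 medical
    cost, median/q1/q3 number of medical visits (per-patient-day collapse,
    mirroring the dental visit definition), % complex-chronic, % with any
    dental visit, and median/q1/q3 age at the first dental visit (NaN when
    a group has no pre-24 dental exposure).
    """
    ids = list(labels_by_patient.index)
    months = age_months(claims["service_age_days"])
    pre24 = claims[months < 24]

    medical = pre24[pre24["claim_class"] == "MEDICAL"]
    med_cost = medical.groupby("patient_id")["paid"].sum()
    med_visits = medical.groupby("patient_id")["service_age_days"].nunique()
    dental = pre24[pre24["claim_class"] == "DENTAL"]
    first_day = dental.groupby("patient_id")["service_age_days"].min()
    first_dental = pd.Series(age_months(first_day), index=first_day.index, dtype=float)
    complexity = classify_cohort_complexity(claims, ids, chronic_code_map)

    def row(members) -> dict:
        cost = med_cost.reindex(members).fillna(0.0)
        visits = med_visits.reindex(members).fillna(0).astype(int)
        fd = first_dental.reindex(members).dropna()
        cx = complexity.reindex(members)
        med, q1, q3 = _median_iqr(cost)
        vmed, vq1, vq3 = _median_iqr(visits)
        amed, aq1, aq3 = _median_iqr(fd) if len(fd) else (np.nan, np.nan, np.nan)
        return {
            "n": len(members),
            "medical_cost_median": med, "medical_cost_q1": q1, "medical_cost_q3": q3,
            "medical_visits_median": vmed, "medical_visits_q1": vq1, "medical_visits_q3": vq3,
            "pct_complex_chronic": 100.0 * float((cx == ComplexityLevel.COMPLEX_CHRONIC).mean()),
            "pct_any_dental_visit": 100.0 * len(fd) / len(members),
            "first_dental_age_median": amed, "first_dental_age_q1": aq1, "first_dental_age_q3": aq3,
        }

    rows = {}
    for label in LABEL_ORDER:
        members = labels_by_patient.index[labels_by_patient == label]
        if len(members):
            rows[label.value] = row(members)
    rows["Overall"] = row(pd.Index(ids))
    return pd.DataFrame(rows).T.rename_axis("subgroup")


def reproduce_on_stratum(claims: pd.DataFrame, patients: pd.DataFrame, predicate,
                         min_n: int = 500, **analysis_kwargs):
    """Re-run the full curves -> clustering -> labeling -> summaries analysis
    on the sub-cohort selected by *predicate* (a boolean function of a
    patient row, or a boolean Series indexed like *patients*).

    Returns the :class:`ecdc.pipeline.CohortAnalysis` of the subset.  With a
    predicate selecting everyone (and the same seed) the result is identical
    to the main run.  Raises ``ValueError`` when the subset is smaller than
    *min_n* or structurally unable to support the five-cluster solution.
    """
    from .pipeline import analyze_cohort  # local import: avoids a module cycle

    if callable(predicate):
        mask = patients.apply(predicate, axis=1).astype(bool)
    else:
        mask = pd.Series(predicate, index=patients.index).astype(bool)
    sub_patients = patients[mask.to_numpy()].reset_index(drop=True)
    if len(sub_patients) < min_n:
        raise ValueError(f"stratum has {len(sub_patients)} patients; need >= {min_n}")
    keep = set(sub_patients["patient_id"])
    sub_claims = claims[claims["patient_id"].isin(keep)].reset_index(drop=True)
    return analyze_cohort(sub_claims, sub_patients, **analysis_kwargs)
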