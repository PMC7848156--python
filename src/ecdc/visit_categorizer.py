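"""Collapse dental claim lines to per-patient-day visits and categorize them.

A dental visit is the use of any dental services during a single day.  Each
visit receives exactly one of four mutually exclusive categories, assigned
in a strict priority order (highest first):

1. ``T_OR``  — treatment visit with operating-room (general anesthesia) use
2. ``T_NOR`` — treatment visit without operating-room use
3. ``PREVENTIVE`` — preventive care
4. ``OTHER`` — anything else (exams, radiographs, ...)

Treatment is identified by CDT code ranges D2000-D2999 (restorative),
D3000-D3999 (root canal), D7000-D7999 (oral surgery).  Operating-room use is
identified by a set of CDT anesthesia/facility codes, or by an OR-associated
CPT code in combination with a dental-disease ICD diagnosis (ICD-9 520-529,
ICD-10 K00-K14 or M26-M27).  Preventive care is CDT D1000-D1999.  Evidence
is pooled over the whole day's codes: categories describe the visit, not the
individual line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd
import yaml

from .claims_io import age_months


class VisitCategory(IntEnum):
    """Visit categories; smaller value = higher assignment priority."""

    T_OR = 0
    T_NOR = 1
    PREVENTIVE = 2
    OTHER = 3


#: Fixed category order used for feature-vector blocks.
CATEGORY_ORDER = [
    VisitCategory.T_OR,
    VisitCategory.T_NOR,
    VisitCategory.PREVENTIVE,
    VisitCategory.OTHER,
]

_CDT_RE = re.compile(r"^D(\d{4})$")


@dataclass
class CodeTables:
    """Configurable procedure/diagnosis code tables driving categorization.

    ``or_cpt`` carries the literal strings of the OR-associated CPT codes;
    codes are compared verbatim (no zero padding), and the table is
    config-editable because one printed code ("0360") is not a standard
    5-digit CPT code.
    """

    treatment_cdt_ranges: list[tuple[int, int]] = field(
        default_factory=lambda: [(2000, 2999), (3000, 3999), (7000, 7999)]
    )
    or_cdt: set[str] = field(default_factory=lambda: {"D9420", "D9219", "D9220", "D9221", "D9223"})
    or_cpt: set[str] = field(default_factory=lambda: {"41899", "00170", "0360"})
    icd9_dental_range: tuple[int, int] = (520, 529)
    icd10_dental_prefixes: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("K", 0, 14), ("M", 26, 27)]
    )
    preventive_cdt_range: tuple[int, int] = (1000, 1999)

    def to_yaml(self, path) -> None:
        doc = {
            "treatment_cdt_ranges": [list(r) for r in self.treatment_cdt_ranges],
            "or_cdt": sorted(self.or_cdt),
            "or_cpt": sorted(self.or_cpt),
            "icd9_dental_range": list(self.icd9_dental_range),
            "icd10_dental_prefixes": [[p, lo, hi] for p, lo, hi in self.icd10_dental_prefixes],
            "preventive_cdt_range": list(self.preventive_cdt_range),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CodeTables":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            treatment_cdt_ranges=[tuple(r) for r in doc["treatment_cdt_ranges"]],
            or_cdt=set(doc["or_cdt"]),
            or_cpt=set(doc["or_cpt"]),
            icd9_dental_range=tuple(doc["icd9_dental_range"]),
            icd10_dental_prefixes=[tuple(p) for p in doc["icd10_dental_prefixes"]],
            preventive_cdt_range=tuple(doc["preventive_cdt_range"]),
        )


DEFAULT_TABLES = CodeTables()


def _cdt_number(code: str) -> int | None:
    m = _CDT_RE.match(code)
    return int(m.group(1)) if m else None


def is_treatment_code(code: str, tables: CodeTables = DEFAULT_TABLES) -> bool:
    """True iff *code* is a CDT code in a treatment range (bounds inclusive)."""
    n = _cdt_number(code)
    if n is None:
        return False
    return any(lo <= n <= hi for lo, hi in tables.treatment_cdt_ranges)


def is_preventive_code(code: str, tables: CodeTables = DEFAULT_TABLES) -> bool:
    """True iff *code* is a CDT code in the preventive range D1000-D1999."""
    n = _cdt_number(code)
    lo, hi = tables.preventive_cdt_range
    return n is not None and lo <= n <= hi


def is_dental_diagnosis(dx: str, tables: CodeTables = DEFAULT_TABLES) -> bool:
    """Prefix-range match of a normalized (undotted, upper-case) ICD code.

    ICD-9: the first three characters parse to an integer in 520..529.
    ICD-10: the three-character category (letter + two digits) falls in
    K00-K14 or M26-M27.
    """
    dx = dx.strip().upper().replace(".", "")
    if len(dx) < 3:
        return False
    head = dx[:3]
    if head.isdigit():
        lo, hi = tables.icd9_dental_range
        return lo <= int(head) <= hi
    if head[1:3].isdigit():
        cat = int(head[1:3])
        return any(head[0] == letter and lo <= cat <= hi for letter, lo, hi in tables.icd10_dental_prefixes)
    return False


def is_or_evidence(codes, diagnoses, tables: CodeTables = DEFAULT_TABLES) -> bool:
    """Operating-room evidence over a day's pooled procedure and diagnosis codes.

    True iff an OR CDT code is present, or an OR CPT code is present together
    with at least one dental-disease diagnosis.
    """
    codes = set(codes)
    if codes & tables.or_cdt:
        return True
    if codes & tables.or_cpt:
        return any(is_dental_diagnosis(d, tables) for d in diagnoses)
    return False


def categorize_day(codes, diagnoses, tables: CodeTables = DEFAULT_TABLES) -> VisitCategory:
    """Category of one visit given the day's pooled codes, by priority."""
    treatment = any(is_treatment_code(c, tables) for c in codes)
    if treatment and is_or_evidence(codes, diagnoses, tables):
        return VisitCategory.T_OR
    if treatment:
        return VisitCategory.T_NOR
    if any(is_preventive_code(c, tables) for c in codes):
        return VisitCategory.PREVENTIVE
    return VisitCategory.OTHER


def collapse_and_categorize(claims: pd.DataFrame, tables: CodeTables = DEFAULT_TABLES) -> pd.DataFrame:
    """Collapse dental claim lines into categorized per-patient-day visits.

    Parameters
    ----------
    claims
        Preprocessed claim table.  Only ``DENTAL`` lines contribute; medical
        lines on the same day supply neither cost nor codes to the visit.
    tables
        Code tables to categorize with.

    Returns
    -------
    DataFrame with one row per (patient_id, service_age_days):
    ``patient_id, service_age_days, age_months, category, cost`` where cost
    is the sum of the day's dental line payments (zero-cost visits are kept:
    a $0 visit is still utilization).
    """
    dental = claims[claims["claim_class"] == "DENTAL"]
    if dental.empty:
        return pd.DataFrame(columns=["patient_id", "service_age_days", "age_months", "category", "cost"])

    # Vectorized per-line flags, then day-level any()/sum() aggregation.
    codes = dental["procedure_code"]
    cdt_num = codes.str.extract(r"^D(\d{4})$", expand=False)
    n = pd.to_numeric(cdt_num, errors="coerce")
    treat = pd.Series(False, index=dental.index)
    for lo, hi in tables.treatment_cdt_ranges:
        treat |= (n >= lo) & (n <= hi)
    lo, hi = tables.preventive_cdt_range
    prev = (n >= lo) & (n <= hi)
    or_cdt = codes.isin(tables.or_cdt)
    or_cpt = codes.isin(tables.or_cpt)
    dental_dx = dental["diagnosis_codes"].map(
        lambda s: any(is_dental_diagnosis(d, tables) for d in s.split(";") if d)
    )

    day = dental.groupby(["patient_id", "service_age_days"], sort=True)
    agg = pd.DataFrame(
        {
            "cost": day["paid"].sum(),
            "treat": treat.groupby([dental["patient_id"], dental["service_age_days"]]).any(),
            "prev": prev.groupby([dental["patient_id"], dental["service_age_days"]]).any(),
            "or_cdt": or_cdt.groupby([dental["patient_id"], dental["service_age_days"]]).any(),
            "or_cpt": or_cpt.groupby([dental["patient_id"], dental["service_age_days"]]).any(),
            "dental_dx": dental_dx.groupby([dental["patient_id"], dental["service_age_days"]]).any(),
        }
    )
    or_evidence = agg["or_cdt"] | (agg["or_cpt"] & agg["dental_dx"])
    category = np.select(
        [agg["treat"] & or_evidence, agg["treat"], agg["prev"]],
        [VisitCategory.T_OR, VisitCategory.T_NOR, VisitCategory.PREVENTIVE],
        default=VisitCategory.OTHER,
    )
    out = agg.reset_index()[["patient_id", "service_age_days"]]
    out["age_months"] = age_months(out["service_age_days"])
    out["category"] = [VisitCategory(c) for c in category]
    out["cost"] = agg["cost"].to_numpy()
    return out
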