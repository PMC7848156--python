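"""Claims/enrollment data model, tabular I/O, and preprocessing rules.

Claim lines are the atomic input record: one billed service line with a
procedure code, diagnosis codes, and a paid amount, stamped with the
patient's age (in days) on the day of service.  Ages are used instead of
calendar dates throughout: the analysis is defined entirely on patient age,
which removes date-of-birth handling.

In memory a claim table is a :class:`pandas.DataFrame` with the columns of
:data:`CLAIM_COLUMNS`; :class:`ClaimLine` / :class:`PatientRecord`
dataclasses are provided for row-level construction and round-tripping.

Preprocessing implements the cohort rules: pharmacy claim lines are
excluded, negative paid amounts (payment adjustments, about 1% of lines in
practice) are clamped to zero, amounts are deflated to 2017 dollars with a
per-service-year index, and eligibility requires continuous enrollment over
months [6, 60).
"""

from __future__ import annotations

import csv
import logging

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Average month length in days; ``age_months = floor(days / DAYS_PER_MONTH)``.
DAYS_PER_MONTH = 30.4375

#: Continuous-enrollment eligibility window, months, half-open.
ELIGIBLE_WINDOW = (6, 60)

#: Analysis window for dental utilization, months, both ends included.
ANALYSIS_WINDOW = (24, 60)

#: Reference year for inflation adjustment.
REFERENCE_YEAR = 2017

CLAIM_CLASSES = ("DENTAL", "MEDICAL", "PHARMACY")

#: Canonical claim-table columns.  ``paid`` is in service-year dollars on
#: input and in 2017 dollars after :func:`adjust_to_2017_dollars`.
CLAIM_COLUMNS = [
    "patient_id",
    "claim_class",
    "service_age_days",
    "procedure_code",
    "diagnosis_codes",
    "paid",
    "service_year",
]

PATIENT_COLUMNS = ["patient_id", "sex", "urban", "enrollment_spans"]


def age_months(service_age_days):
    """Patient age in completed months for an age in days (scalar or array)."""
    return np.floor(np.asarray(service_age_days) / DAYS_PER_MONTH).astype(int)


def normalize_diagnosis(code: str) -> str:
    """Upper-case an ICD code and strip dots: ``"K02.9" -> "K029"``."""
    return code.strip().upper().replace(".", "")


@dataclass
class ClaimLine:
    """One billed service line."""

    patient_id: str
    claim_class: str
    service_age_days: int
    procedure_code: str
    diagnosis_codes: list[str]
    paid: float
    service_year: int

    def __post_init__(self):
        if self.claim_class not in CLAIM_CLASSES:
            raise ValueError(f"unknown claim_class {self.claim_class!r}")
        if self.service_age_days < 0:
            raise ValueError("service_age_days must be non-negative")
        self.diagnosis_codes = [normalize_diagnosis(c) for c in self.diagnosis_codes if c.strip()]


@dataclass
class PatientRecord:
    """Demographics plus enrollment history as half-open month spans."""

    patient_id: str
    sex: str  # "M" | "F"
    urban: bool
    enrollment_spans: list[tuple[int, int]]

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        spans = sorted(tuple(s) for s in self.enrollment_spans)
        for lo, hi in spans:
            if not (0 <= lo < hi):
                raise ValueError(f"invalid enrollment span [{lo}, {hi})")
        for (_, hi), (lo2, _) in zip(spans, spans[1:]):
            if lo2 < hi:
                raise ValueError("enrollment spans overlap")
        self.enrollment_spans = spans

    def covers(self, window: tuple[int, int]) -> bool:
        """True iff the union of spans covers every month of half-open *window*."""
        need = set(range(*window))
        have: set[int] = set()
        for lo, hi in self.enrollment_spans:
            have.update(range(lo, hi))
        return need <= have


@dataclass
class InflationIndex:
    """Service-year -> deflator mapping; multiplying nominal dollars gives 2017 dollars."""

    factors: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        for year, f in self.factors.items():
            if f <= 0:
                raise ValueError(f"deflator for {year} must be positive, got {f}")
        if REFERENCE_YEAR in self.factors and self.factors[REFERENCE_YEAR] != 1.0:
            raise ValueError(f"{REFERENCE_YEAR} must map to 1.0")

    @classmethod
    def identity(cls, years: Iterable[int]) -> "InflationIndex":
        return cls({int(y): 1.0 for y in years})

    def factor(self, year: int) -> float:
        try:
            return self.factors[int(year)]
        except KeyError:
            raise KeyError(f"no inflation factor for service year {year}") from None

    @classmethod
    def from_yaml(cls, path) -> "InflationIndex":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({int(y): float(f) for y, f in raw["factors"].items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"factors": {int(y): float(f) for y, f in self.factors.items()}}, fh)


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_spans(text: str) -> list[tuple[int, int]]:
    spans = []
    for part in str(text).split(";"):
        part = part.strip()
        if not part:
            continue
        lo, hi = part.split("-")
        spans.append((int(lo), int(hi)))
    return spans


def _format_spans(spans: Sequence[tuple[int, int]]) -> str:
    return ";".join(f"{lo}-{hi}" for lo, hi in spans)


def read_claims(path) -> pd.DataFrame:
    """Read a claim-line CSV into the canonical claim table.

    Expected header: ``patient_id, claim_class, service_age_days,
    procedure_code, diagnosis_codes, paid_nominal, service_year`` with
    diagnosis codes semicolon-joined.  Diagnosis codes are normalized
    (upper-case, dots removed).  Malformed rows raise :class:`ValueError`
    naming the offending line number (header = line 1).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = {
        "patient_id",
        "claim_class",
        "service_age_days",
        "procedure_code",
        "diagnosis_codes",
        "paid_nominal",
        "service_year",
    }
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    def _bad_line(mask, what):
        idx = int(np.flatnonzero(mask)[0])
        raise ValueError(f"{path}: line {idx + 2}: {what}")

    bad_class = ~df["claim_class"].isin(CLAIM_CLASSES)
    if bad_class.any():
        _bad_line(bad_class.to_numpy(), f"unknown claim_class {df.loc[bad_class.idxmax(), 'claim_class']!r}")

    age = pd.to_numeric(df["service_age_days"], errors="coerce")
    if age.isna().any() or (age < 0).any() or (age % 1 != 0).any():
        _bad_line((age.isna() | (age < 0) | (age % 1 != 0)).to_numpy(), "bad service_age_days")
    paid = pd.to_numeric(df["paid_nominal"], errors="coerce")
    if paid.isna().any():
        _bad_line(paid.isna().to_numpy(), "bad paid_nominal")
    year = pd.to_numeric(df["service_year"], errors="coerce")
    if year.isna().any() or (year % 1 != 0).any():
        _bad_line((year.isna() | (year % 1 != 0)).to_numpy(), "bad service_year")

    dx = df["diagnosis_codes"].map(
        lambda s: ";".join(normalize_diagnosis(c) for c in s.split(";") if c.strip())
    )
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "claim_class": df["claim_class"],
            "service_age_days": age.astype(int),
            "procedure_code": df["procedure_code"].str.strip().str.upper(),
            "diagnosis_codes": dx,
            "paid": paid.astype(float),
            "service_year": year.astype(int),
        }
    )
    return out


def write_claims(claims: pd.DataFrame, path) -> None:
    """Write the canonical claim table back to the CSV schema (RFC-4180)."""
    out = claims.rename(columns={"paid": "paid_nominal"})
    cols = [
        "patient_id",
        "claim_class",
        "service_age_days",
        "procedure_code",
        "diagnosis_codes",
        "paid_nominal",
        "service_year",
    ]
    out[cols].to_csv(path, index=False, float_format="%.2f", quoting=csv.QUOTE_MINIMAL, lineterminator="\n")


def read_patients(path) -> pd.DataFrame:
    """Read the patient/enrollment CSV (patient_id, sex, urban, enrollment_spans)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(PATIENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad_sex = ~df["sex"].isin(("M", "F"))
    if bad_sex.any():
        raise ValueError(f"{path}: line {int(np.flatnonzero(bad_sex)[0]) + 2}: bad sex")
    return pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "sex": df["sex"],
            "urban": df["urban"].astype(int).astype(bool),
            "enrollment_spans": df["enrollment_spans"],
        }
    )


def write_patients(patients: pd.DataFrame, path) -> None:
    out = patients.copy()
    out["urban"] = out["urban"].astype(int)
    out[PATIENT_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def claims_frame(lines: Iterable[ClaimLine]) -> pd.DataFrame:
    """Build a claim table from :class:`ClaimLine` records."""
    rows = [
        (
            c.patient_id,
            c.claim_class,
            c.service_age_days,
            c.procedure_code,
            ";".join(c.diagnosis_codes),
            c.paid,
            c.service_year,
        )
        for c in lines
    ]
    return pd.DataFrame(rows, columns=CLAIM_COLUMNS)


def iter_claim_lines(claims: pd.DataFrame) -> Iterable[ClaimLine]:
    for row in claims.itertuples(index=False):
        yield ClaimLine(
            row.patient_id,
            row.claim_class,
            int(row.service_age_days),
            row.procedure_code,
            [c for c in row.diagnosis_codes.split(";") if c],
            float(row.paid),
            int(row.service_year),
        )


def patients_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = [(p.patient_id, p.sex, p.urban, _format_spans(p.enrollment_spans)) for p in records]
    return pd.DataFrame(rows, columns=PATIENT_COLUMNS)


def iter_patient_records(patients: pd.DataFrame) -> Iterable[PatientRecord]:
    for row in patients.itertuples(index=False):
        yield PatientRecord(row.patient_id, row.sex, bool(row.urban), _parse_spans(row.enrollment_spans))


# ---------------------------------------------------------------------------
# Preprocessing rules


def drop_pharmacy(claims: pd.DataFrame) -> pd.DataFrame:
    """Exclude pharmacy claim lines; dental and medical lines pass through."""
    return claims[claims["claim_class"] != "PHARMACY"].reset_index(drop=True)


def clamp_negative_payments(claims: pd.DataFrame) -> pd.DataFrame:
    """Replace negative paid amounts (payment adjustments) by zero."""
    n = int((claims["paid"] < 0).sum())
    if n:
        logger.info("clamped %d negative paid amounts to zero", n)
    out = claims.copy()
    out["paid"] = out["paid"].clip(lower=0.0)
    return out


def adjust_to_2017_dollars(claims: pd.DataFrame, index: InflationIndex) -> pd.DataFrame:
    """Deflate paid amounts to 2017 dollars using per-service-year factors."""
    years = claims["service_year"].unique()
    missing = [int(y) for y in years if int(y) not in index.factors]
    if missing:
        raise KeyError(f"no inflation factor for service year(s) {sorted(missing)}")
    out = claims.copy()
    out["paid"] = out["paid"] * out["service_year"].map(index.factors)
    return out


def filter_eligible(patients: pd.DataFrame, window: tuple[int, int] = ELIGIBLE_WINDOW) -> list[str]:
    """Patient ids whose enrollment spans cover every month of half-open *window*.

    Continuity is checked at month granularity; abutting spans count as
    continuous coverage.
    """
    keep = []
    for row in patients.itertuples(index=False):
        rec = PatientRecord(row.patient_id, row.sex, bool(row.urban), _parse_spans(row.enrollment_spans))
        if rec.covers(window):
            keep.append(rec.patient_id)
    return keep


def preprocess(
    claims: pd.DataFrame,
    index: InflationIndex | None = None,
    exclude_pharmacy: bool = True,
) -> pd.DataFrame:
    """Standard preprocessing: drop pharmacy, clamp negatives, adjust to 2017 USD.

    With ``index=None`` an identity index over the years present is used
    (appropriate when amounts are already in constant dollars).
    """
    out = drop_pharmacy(claims) if exclude_pharmacy else claims
    out = clamp_negative_payments(out)
    if index is None:
        index = InflationIndex.identity(out["service_year"].unique())
    return adjust_to_2017_dollars(out, index)
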