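"""Per-patient cumulative cost curves and fixed-length clustering vectors.

A cost curve is the cumulative 2017-dollar cost of a patient over age.  If a
child incurs costs C1, C2, C3 at three visits by 40 months, the curve at 40
months is C1 + C2 + C3; a fourth visit at 45 months raises it to
C1 + C2 + C3 + C4.  Curves are sampled on a monthly age grid (default 24..60
inclusive, 37 points) and built separately for the four visit categories.
Each patient's clustering feature vector is the concatenation of the four
category curves in the fixed order T_OR, T_NOR, PREVENTIVE, OTHER (length
4 x 37 = 148 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .visit_categorizer import CATEGORY_ORDER, VisitCategory

#: Length of the analysis window in years (24-60 months); divisor for
#: annualizing window-total costs.
WINDOW_YEARS = 3.0


@dataclass(frozen=True)
class AgeGrid:
    """Ordered integer month grid; default 24, 25, ..., 60."""

    start: int = 24
    stop: int = 60

    def __post_init__(self):
        if self.stop <= self.start:
            raise ValueError("grid stop must exceed start")

    @property
    def months(self) -> np.ndarray:
        return np.arange(self.start, self.stop + 1)

    def __len__(self) -> int:
        return self.stop - self.start + 1


@dataclass
class CostCurve:
    """Cumulative cost per category on a shared grid for one patient."""

    patient_id: str
    grid: AgeGrid
    curves: dict = field(default_factory=dict)  # VisitCategory -> np.ndarray


def build_cost_curve(visits: pd.DataFrame, grid: AgeGrid = AgeGrid()) -> CostCurve:
    """Cumulative per-category cost curve for a single patient's visits.

    ``curve_c(m)`` is the summed cost of category-c visits at ages <= m
    months.  Visits outside the grid window raise ``ValueError`` — filtering
    to the analysis window is the caller's job.
    """
    pids = visits["patient_id"].unique()
    if len(pids) > 1:
        raise ValueError("build_cost_curve expects visits of a single patient")
    pid = pids[0] if len(pids) else ""
    months = visits["age_months"].to_numpy()
    if len(months) and (months.min() < grid.start or months.max() > grid.stop):
        raise ValueError(f"visit outside grid window [{grid.start}, {grid.stop}]")
    curves = {}
    for cat in CATEGORY_ORDER:
        sel = visits[visits["category"] == cat]
        per_month = np.zeros(len(grid))
        if len(sel):
            np.add.at(per_month, sel["age_months"].to_numpy() - grid.start, sel["cost"].to_numpy())
        curves[cat] = np.cumsum(per_month)
    return CostCurve(pid, grid, curves)


def vectorize(curve: CostCurve, grid: AgeGrid = AgeGrid()) -> np.ndarray:
    """Concatenate the four category curves in fixed order into one vector."""
    if curve.grid != grid:
        raise ValueError("grid mismatch")
    return np.concatenate([curve.curves[c] for c in CATEGORY_ORDER])


def annual_cost(curve: CostCurve) -> float:
    """Annualized window cost: total over 24-60 months divided by 3 years."""
    total = sum(float(v[-1]) for v in curve.curves.values())
    return total / WINDOW_YEARS


def feature_names(grid: AgeGrid = AgeGrid()) -> list[str]:
    return [f"{cat.name}_m{m}" for cat in CATEGORY_ORDER for m in grid.months]


def curve_matrix(
    visits: pd.DataFrame,
    patient_ids,
    grid: AgeGrid = AgeGrid(),
) -> pd.DataFrame:
    """Feature matrix of concatenated cumulative curves for a whole cohort.

    Parameters
    ----------
    visits
        Categorized visit table (all patients).  Visits outside the grid
        window raise ``ValueError``.
    patient_ids
        Row universe.  Patients with no visits get all-zero rows, which is
        what makes zero-utilization patients representable.

    Returns
    -------
    DataFrame (n_patients x 4|grid|) indexed by patient_id with
    :func:`feature_names` columns, in dollars.
    """
    patient_ids = list(patient_ids)
    row = {pid: i for i, pid in enumerate(patient_ids)}
    T = len(grid)
    X = np.zeros((len(patient_ids), 4, T))
    if len(visits):
        months = visits["age_months"].to_numpy()
        if months.min() < grid.start or months.max() > grid.stop:
            raise ValueError(f"visit outside grid window [{grid.start}, {grid.stop}]")
        unknown = set(visits["patient_id"]) - set(row)
        if unknown:
            raise ValueError(f"visits for patients not in patient_ids, e.g. {sorted(unknown)[:3]}")
        r = visits["patient_id"].map(row).to_numpy()
        c = visits["category"].astype(int).to_numpy()
        m = months - grid.start
        np.add.at(X, (r, c, m), visits["cost"].to_numpy())
    X = np.cumsum(X, axis=2).reshape(len(patient_ids), 4 * T)
    return pd.DataFrame(X, index=pd.Index(patient_ids, name="patient_id"), columns=feature_names(grid))


def annual_costs(features: pd.DataFrame, grid: AgeGrid = AgeGrid()) -> pd.Series:
    """Per-patient annual cost from a feature matrix (window total / 3)."""
    T = len(grid)
    ends = [b * T + (T - 1) for b in range(4)]
    return features.iloc[:, ends].sum(axis=1) / WINDOW_YEARS


class CostCurveVectorizer(BaseEstimator, TransformerMixin):
    """Transformer from categorized visit tables to clustering vectors.

    ``transform`` takes a visit table (output of
    :func:`ecdc.visit_categorizer.collapse_and_categorize`, filtered to the
    analysis window) and returns the cumulative-curve feature matrix.  The
    patient universe must be given explicitly so that patients with zero
    dental utilization appear as all-zero rows.

    Parameters
    ----------
    patient_ids : sequence of str
        Cohort row universe.
    grid : AgeGrid
        Monthly sampling grid, default 24..60.
    """

    def __init__(self, patient_ids=None, grid: AgeGrid = AgeGrid()):
        self.patient_ids = patient_ids
        self.grid = grid

    def fit(self, X: pd.DataFrame, y=None):
        if self.patient_ids is None:
            raise ValueError("patient_ids must be provided")
        self.feature_names_ = feature_names(self.grid)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "feature_names_")
        return curve_matrix(X, self.patient_ids, self.grid)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_)
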