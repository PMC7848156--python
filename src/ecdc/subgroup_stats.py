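"""Cohort and subgroup cost statistics.

Produces the demographic PMPY (per-member-per-year) segmentation with
male-vs-female Welch t-tests, the per-subgroup annual-cost summary table
(n, %, median, IQR, mean, share of total cost), and the Kruskal-Wallis
comparison of annual costs across clusters.

Conventions: age bands are one year wide ([24,36), [36,48), [48,60]; the
last band is closed so month-60 visits count), so the mean band cost over a
stratum IS the PMPY cost; quantiles use linear interpolation between order
statistics; the Kruskal-Wallis statistic is tie-corrected (zero-utilization
cohorts produce many tied zero costs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import LABEL_ORDER, SubgroupLabel

DEFAULT_BANDS = [(24, 36), (36, 48), (48, 60)]


def _band_mask(months: np.ndarray, band: tuple[int, int], last: bool) -> np.ndarray:
    lo, hi = band
    return (months >= lo) & ((months <= hi) if last else (months < hi))


def _per_patient_band_costs(visits: pd.DataFrame, patient_ids, bands) -> pd.DataFrame:
    """Per-patient cost per age band (patients without visits count $0)."""
    idx = pd.Index(patient_ids, name="patient_id")
    out = pd.DataFrame(0.0, index=idx, columns=[f"{lo}-{hi}" for lo, hi in bands])
    months = visits["age_months"].to_numpy()
    for i, band in enumerate(bands):
        sel = visits[_band_mask(months, band, last=(i == len(bands) - 1))]
        sums = sel.groupby("patient_id")["cost"].sum()
        out.loc[sums.index, out.columns[i]] = sums
    out["total"] = out.sum(axis=1)
    return out


def pmpy_by_stratum(visits: pd.DataFrame, patients: pd.DataFrame, bands=DEFAULT_BANDS) -> pd.DataFrame:
    """PMPY dental cost by gender stratum with Welch t-tests per band.

    Rows: Overall / Male / Female means per band and window total, plus a
    ``t-test p`` row comparing male vs female per column.  Zero-variance
    comparisons yield NaN p-values (flagged, not an error).
    """
    band_costs = _per_patient_band_costs(visits, patients["patient_id"], bands)
    sex = patients.set_index("patient_id")["sex"].reindex(band_costs.index)
    male = band_costs[sex == "M"]
    female = band_costs[sex == "F"]
    if len(male) == 0 or len(female) == 0:
        raise ValueError("empty gender stratum")
    rows = {
        "Overall": band_costs.mean(),
        "Male": male.mean(),
        "Female": female.mean(),
    }
    pvals = {}
    for col in band_costs.columns:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(male[col], female[col], equal_var=False)
        pvals[col] = float(res.pvalue)
    out = pd.DataFrame(rows).T
    out.loc["t-test p"] = pd.Series(pvals)
    out.insert(0, "pct_of_population", [100.0, 100.0 * len(male) / len(band_costs),
                                        100.0 * len(female) / len(band_costs), np.nan])
    return out


@dataclass
class SubgroupSummary:
    label: SubgroupLabel
    n: int
    pct_of_population: float
    median_annual_cost: float
    iqr: tuple[float, float]
    mean_annual_cost: float
    pct_of_total_annual_cost: float


def subgroup_cost_summary(labels_by_patient: pd.Series, annual_costs: pd.Series) -> pd.DataFrame:
    """Per-subgroup annual-cost summary (the five-subgroup cost table).

    Parameters
    ----------
    labels_by_patient
        :class:`SubgroupLabel` per patient_id.
    annual_costs
        Annual dental cost per patient_id (window total / 3).

    Returns a DataFrame indexed by subgroup label value with columns
    ``n, pct_of_population, median_annual_cost, q1, q3, mean_annual_cost,
    pct_of_total_annual_cost``; the shares sum to 100 (up to rounding) and
    the n column sums to the cohort size.
    """
    costs = annual_costs.reindex(labels_by_patient.index)
    total = float(costs.sum())
    n_all = len(labels_by_patient)
    rows = []
    for label in LABEL_ORDER:
        sel = costs[labels_by_patient == label]
        if len(sel) == 0:
            continue
        q1, med, q3 = np.percentile(sel, [25, 50, 75])
        rows.append(
            {
                "subgroup": label.value,
                "n": len(sel),
                "pct_of_population": 100.0 * len(sel) / n_all,
                "median_annual_cost": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "mean_annual_cost": float(sel.mean()),
                "pct_of_total_annual_cost": 100.0 * float(sel.sum()) / total if total > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("subgroup")


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-squared p-value (k-1 df).

    *groups* is a sequence of >= 2 nonempty samples.  Identical values in
    every group give (H, p) = (0, 1) rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
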