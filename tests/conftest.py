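import numpy as np
import pandas as pd
import pytest

from ecdc import claims_io
from ecdc.pipeline import analyze_cohort
from ecdc.synthetic_data import GeneratorConfig, generate_cohort
from ecdc.visit_categorizer import VisitCategory, collapse_and_categorize


def make_visits(rows):
    """Visit table from (patient_id, age_months, category, cost) tuples."""
    df = pd.DataFrame(rows, columns=["patient_id", "age_months", "category", "cost"])
    df.insert(1, "service_age_days", (df["age_months"] * claims_io.DAYS_PER_MONTH).astype(int) + 1)
    return df[["patient_id", "service_age_days", "age_months", "category", "cost"]]


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic cohort of 2,000 patients (seed 42), preprocessed."""
    claims, patients, truth = generate_cohort(GeneratorConfig(n_patients=2000, seed=42))
    return claims_io.preprocess(claims), patients, truth


@pytest.fixture(scope="session")
def small_visits(small_cohort):
    claims, _, _ = small_cohort
    return collapse_and_categorize(claims)


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    """Five-cluster analysis of the small cohort (k fixed, no elbow sweep)."""
    claims, patients, _ = small_cohort
    return analyze_cohort(claims, patients, seed=42, k=5, compute_quality=False)
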