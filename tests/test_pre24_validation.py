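"""Complexity stratifier, pre-24-month profiles, and stratum reproduction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ecdc import claims_io
from ecdc.clustering import SubgroupLabel
from ecdc.pre24_validation import (ComplexityLevel, DEFAULT_CHRONIC_CODE_MAP,
                                   classify_complexity, load_chronic_code_map,
                                   pre24_profile, reproduce_on_stratum,
                                   save_chronic_code_map)

TOY_MAP = {
    "Q24": {"system": "cardiovascular", "progressive": False},
    "G80": {"system": "neurologic", "progressive": False},
    "J45": {"system": "respiratory", "progressive": False},
    "K21": {"system": "gastrointestinal", "progressive": False},
    "D61": {"system": "hematologic", "progressive": True},
    "C91": {"system": "malignancy", "progressive": True},
}
TOY_CODES = ["Q249", "G809", "J459", "K219", "D619", "C9100", "Z001"]


def oracle_level(codes):
    systems, progressive = set(), False
    for c in codes:
        for pre, info in TOY_MAP.items():
            if c.startswith(pre):
                systems.add(info["system"])
                progressive |= info["progressive"]
    if progressive or len(systems) >= 2:
        return ComplexityLevel.COMPLEX_CHRONIC
    return ComplexityLevel.NONCOMPLEX_CHRONIC if systems else ComplexityLevel.NO_CHRONIC


class TestComplexity:
    def test_exhaustive_rule_table(self):
        """All subsets of a 7-code alphabet match the independent rule oracle."""
        for r in range(len(TOY_CODES) + 1):
            for combo in itertools.combinations(TOY_CODES, r):
                assert classify_complexity(combo, TOY_MAP) is oracle_level(combo), combo

    @pytest.mark.parametrize(
        "codes,expected",
        [(["Q249", "G809"], ComplexityLevel.COMPLEX_CHRONIC),    # two body systems
         (["J459"], ComplexityLevel.NONCOMPLEX_CHRONIC),         # one system, no flag
         (["C9100"], ComplexityLevel.COMPLEX_CHRONIC),           # malignancy flag alone
         (["Z001"], ComplexityLevel.NO_CHRONIC),
         ([], ComplexityLevel.NO_CHRONIC)],
    )
    def test_named_cases(self, codes, expected):
        assert classify_complexity(codes, TOY_MAP) is expected

    def test_dotted_codes_normalized(self):
        assert classify_complexity(["q24.9", "g80.9"], TOY_MAP) is ComplexityLevel.COMPLEX_CHRONIC

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_complexity(["Q249"], {})

    def test_map_yaml_round_trip(self, tmp_path):
        path = tmp_path / "chronic.yaml"
        save_chronic_code_map(DEFAULT_CHRONIC_CODE_MAP, path)
        assert load_chronic_code_map(path) == DEFAULT_CHRONIC_CODE_MAP


def tiny_claims(rows):
    """rows: (pid, claim_class, month, code, dx, paid)."""
    return claims_io.claims_frame(
        [claims_io.ClaimLine(p, cc, int(m * 30.4375) + 1, code, list(dx), paid, 2016)
         for p, cc, m, code, dx, paid in rows]
    )


class TestPre24Profile:
    @staticmethod
    def cohort():
        rows = [
            # subgroup A: two patients with medical + dental history
            ("A1", "MEDICAL", 3, "99213", ("Q249", "G809"), 100.0),
            ("A1", "MEDICAL", 10, "99213", (), 100.0),
            ("A1", "DENTAL", 18, "D0120", (), 40.0),
            ("A2", "MEDICAL", 5, "99213", (), 300.0),
            # subgroup B: no pre-24 dental claims at all
            ("B1", "MEDICAL", 8, "99213", ("J459",), 50.0),
            ("B2", "MEDICAL", 40, "99213", (), 999.0),  # after 24m: ignored
        ]
        claims = tiny_claims(rows)
        patients = pd.DataFrame({"patient_id": ["A1", "A2", "B1", "B2"], "sex": "F",
                                 "urban": False, "enrollment_spans": "0-60"})
        labels = pd.Series([SubgroupLabel.EARLY_ONSET] * 2 + [SubgroupLabel.ZERO_UTIL] * 2,
                           index=pd.Index(["A1", "A2", "B1", "B2"], name="patient_id"))
        return claims, patients, labels

    def test_group_statistics(self):
        claims, patients, labels = self.cohort()
        prof = pre24_profile(claims, patients, labels, TOY_MAP)
        early = prof.loc["early_onset"]
        assert early["medical_cost_median"] == pytest.approx(250.0)  # {200, 300}
        assert early["medical_visits_median"] == pytest.approx(1.5)
        assert early["pct_complex_chronic"] == pytest.approx(50.0)
        assert early["pct_any_dental_visit"] == pytest.approx(50.0)
        assert early["first_dental_age_median"] == pytest.approx(18.0)

    def test_no_dental_group_reported_missing(self):
        claims, patients, labels = self.cohort()
        prof = pre24_profile(claims, patients, labels, TOY_MAP)
        zero = prof.loc["zero_util"]
        assert zero["pct_any_dental_visit"] == 0.0
        assert np.isnan(zero["first_dental_age_median"])

    def test_overall_row_is_pooled_not_averaged(self):
        claims, patients, labels = self.cohort()
        prof = pre24_profile(claims, patients, labels, TOY_MAP)
        # pooled medical costs {200, 300, 50, 0} -> median 125; mean of group
        # medians would be (250 + 25) / 2 = 137.5
        assert prof.loc["Overall", "medical_cost_median"] == pytest.approx(125.0)
        assert prof.loc["Overall", "n"] == 4

    def test_recovers_planted_complexity_gradient(self, small_cohort, small_analysis):
        claims, patients, _ = small_cohort
        prof = pre24_profile(claims, patients, small_analysis.labels_by_patient)
        # planted: zero-utilization has the lowest complex share (13.6%) and
        # the lowest pre-24 medical cost median ($5,744)
        assert prof.loc["zero_util", "pct_complex_chronic"] == pytest.approx(13.6, abs=3.0)
        assert prof.loc["zero_util", "medical_cost_median"] == \
            prof["medical_cost_median"].drop("Overall").min()
        assert prof.loc["zero_util", "pct_any_dental_visit"] == pytest.approx(10.4, abs=3.0)


class TestReproduceOnStratum:
    def test_full_cohort_predicate_is_identity(self, small_cohort, small_analysis):
        claims, patients, _ = small_cohort
        rerun = reproduce_on_stratum(claims, patients, lambda row: True,
                                     seed=42, k=5, compute_quality=False)
        pd.testing.assert_series_equal(rerun.labels_by_patient, small_analysis.labels_by_patient)
        pd.testing.assert_frame_equal(rerun.subgroup_table, small_analysis.subgroup_table)

    def test_small_stratum_rejected(self, small_cohort):
        claims, patients, _ = small_cohort
        with pytest.raises(ValueError, match="need >="):
            reproduce_on_stratum(claims, patients, lambda row: row["patient_id"] == "P000000")

    def test_degenerate_stratum_fails_cleanly(self, small_cohort, small_analysis):
        """A stratum holding a single planted cluster cannot support k=5."""
        claims, patients, _ = small_cohort
        zero_ids = set(small_analysis.labels_by_patient
                       [small_analysis.labels_by_patient == SubgroupLabel.ZERO_UTIL].index)
        with pytest.raises(ValueError):
            reproduce_on_stratum(claims, patients,
                                 lambda row: row["patient_id"] in zero_ids,
                                 min_n=50, seed=0, k=5, compute_quality=False)

    def test_urban_stratum_recovers_urban_mixture(self, small_cohort):
        claims, patients, truth = small_cohort
        urban = reproduce_on_stratum(claims, patients, lambda row: bool(row["urban"]),
                                     min_n=100, seed=42, k=5, compute_quality=False)
        planted = truth.set_index("patient_id").loc[urban.labels_by_patient.index]
        got = urban.labels_by_patient.map(lambda l: l.value)
        assert (planted["urban"] == 1).all()
        assert (planted["subgroup"] == got).mean() > 0.9
        # urban mixture: zero-utilization dominates (planted 57.1%)
        zero_pct = urban.subgroup_table.loc["zero_util", "pct_of_population"]
        assert zero_pct == pytest.approx(57.1, abs=8.0)
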