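"""k-means, k selection, quality scores, representatives, and labeling."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans as SkKMeans
from sklearn.metrics import adjusted_rand_score

from conftest import make_visits
from ecdc.clustering import (CH_SENTINEL, SubgroupLabel, TrajectoryKMeans,
                             calinski_harabasz, elbow_select_k, kmeans,
                             label_clusters, random_clustering_baseline,
                             representative_patient, silhouette)
from ecdc.visit_categorizer import VisitCategory


def blobs(centers, n_per, spread, seed=0, dim=2):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i, c in enumerate(centers):
        X.append(c + spread * rng.standard_normal((n_per, dim)))
        y.extend([i] * n_per)
    return np.vstack(X), np.array(y)


class TestKMeans:
    def test_separable_point_masses_perfect_split(self):
        X = np.array([[0.0, 0.0]] * 10 + [[100.0, 100.0]] * 10)
        X += np.arange(20)[:, None] * 1e-9  # make vectors distinct
        m = TrajectoryKMeans(2, random_state=0, transform="none", scale=False).fit(X)
        assert m.inertia_ == pytest.approx(0.0, abs=1e-10)
        assert len(set(m.labels_[:10])) == 1 and len(set(m.labels_[10:])) == 1

    def test_k_equals_n_zero_inertia(self):
        X = np.arange(6, dtype=float)[:, None]
        m = TrajectoryKMeans(6, random_state=0, transform="none", scale=False).fit(X)
        assert m.inertia_ == pytest.approx(0.0)

    @pytest.mark.parametrize("k", [1, 0, 25])
    def test_invalid_k_rejected(self, k):
        X = np.arange(20, dtype=float)[:, None]
        with pytest.raises(ValueError):
            TrajectoryKMeans(k).fit(X)

    def test_recovers_separated_gaussians(self):
        X, y = blobs([np.zeros(2), np.full(2, 50.0), np.full(2, 100.0)], 10, 0.1, seed=1)
        m = kmeans(X, 3, seed=0, transform="none", scale=False)
        # oracle: assignment to the nearest generating mean
        assert adjusted_rand_score(y, m.labels_) == 1.0

    def test_inertia_history_non_increasing(self):
        X, _ = blobs([np.zeros(2), np.ones(2) * 3], 100, 1.5, seed=2)
        m = kmeans(X, 4, seed=3, transform="none", scale=False)
        assert all(b <= a + 1e-9 for a, b in zip(m.inertia_history_, m.inertia_history_[1:]))

    def test_matches_sklearn_inertia(self):
        X, _ = blobs([np.zeros(3), np.ones(3) * 4, np.array([8.0, 0, 0])], 60, 1.0, seed=4, dim=3)
        ours = kmeans(X, 3, seed=0, transform="none", scale=False)
        ref = SkKMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        assert ours.inertia_ == pytest.approx(ref.inertia_, rel=1e-3)

    def test_deterministic_under_seed(self):
        X, _ = blobs([np.zeros(2), np.ones(2) * 5], 50, 1.0, seed=5)
        a = kmeans(X, 2, seed=11, transform="none", scale=False)
        b = kmeans(X, 2, seed=11, transform="none", scale=False)
        assert (a.labels_ == b.labels_).all() and a.inertia_ == b.inertia_

    def test_predict_matches_fit_labels(self):
        X, _ = blobs([np.zeros(2), np.ones(2) * 5], 50, 0.3, seed=6)
        m = kmeans(X, 2, seed=0, transform="none", scale=False)
        assert (m.predict(X) == m.labels_).all()


class TestElbow:
    def test_five_separated_blobs(self):
        centers = [np.array([i * 40.0, -i * 25.0]) for i in range(5)]
        X, _ = blobs(centers, 40, 0.8, seed=7)
        assert elbow_select_k(X, range(2, 9), seed=0, transform="none", scale=False).k == 5

    def test_two_blobs(self):
        X, _ = blobs([np.zeros(2), np.full(2, 30.0)], 60, 1.0, seed=8)
        assert elbow_select_k(X, range(2, 9), seed=0, transform="none", scale=False).k == 2

    def test_identical_points_smallest_k(self):
        X = np.ones((50, 3))
        res = elbow_select_k(X, range(2, 7), seed=0, transform="none", scale=False)
        assert res.k == 2 and res.inertias == [0.0] * 5

    def test_short_k_range_rejected(self):
        with pytest.raises(ValueError):
            elbow_select_k(np.ones((10, 2)), [2, 3], seed=0)


class TestQualityScores:
    def test_silhouette_tight_far_clusters_near_one(self):
        X, y = blobs([np.zeros(2), np.full(2, 1e6)], 30, 1.0, seed=9)
        assert silhouette(X, y) > 1 - 1e-5

    def test_silhouette_random_labels_near_zero(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(size=(500, 4))
        s = silhouette(X, rng.integers(0, 3, size=500))
        assert abs(s) < 0.1

    def test_single_cluster_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            silhouette(X, np.zeros(10))
        with pytest.raises(ValueError):
            calinski_harabasz(X, np.zeros(10))

    def test_ch_perfect_separation_sentinel(self):
        X = np.array([[0.0, 0.0]] * 5 + [[9.0, 9.0]] * 5)
        raw, norm = calinski_harabasz(X, np.array([0] * 5 + [1] * 5))
        assert raw == CH_SENTINEL and norm == pytest.approx(1.0)

    def test_ch_random_labels_near_one(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(500, 3))
        raws = [calinski_harabasz(X, rng.integers(0, 4, 500))[0] for _ in range(20)]
        assert 0.7 < np.mean(raws) < 1.3

    def test_ch_dispersion_ratio_invariant_under_duplication(self):
        """Duplicating the dataset leaves the between/within dispersion ratio
        unchanged; the df-scaled statistic transforms exactly by
        (2n-k)/(n-k)."""
        X, y = blobs([np.zeros(2), np.full(2, 4.0)], 250, 1.0, seed=12)
        n, k = len(X), 2
        raw, _ = calinski_harabasz(X, y)
        raw2, _ = calinski_harabasz(np.vstack([X, X]), np.concatenate([y, y]))
        assert raw2 == pytest.approx(raw * (2 * n - k) / (n - k), rel=1e-9)
        ratio = raw * (k - 1) / (n - k)
        ratio2 = raw2 * (k - 1) / (2 * n - k)
        assert ratio2 == pytest.approx(ratio, rel=1e-9)

    def test_random_baseline_reproducible_and_dominated(self):
        centers = [np.array([i * 30.0, i * 10.0]) for i in range(5)]
        X, _ = blobs(centers, 100, 1.0, seed=13)
        m = kmeans(X, 5, seed=0, transform="none", scale=False)
        ours = silhouette(X, m.labels_)
        base1 = random_clustering_baseline(X, 5, seed=1, reps=1)
        base2 = random_clustering_baseline(X, 5, seed=1, reps=1)
        assert base1 == base2  # determinism
        assert base1.silhouette < 0.1 < ours
        assert base1.silhouette < ours


class TestRepresentative:
    def frame(self, X):
        return pd.DataFrame(X, index=[f"P{i:03d}" for i in range(len(X))])

    def test_singleton_cluster(self):
        X = self.frame(np.array([[0.0], [100.0], [101.0]]))
        m = kmeans(X, 2, seed=0, transform="none", scale=False)
        lone = m.labels_[0]
        assert representative_patient(m, X, lone).patient_id == "P000"

    def test_symmetric_tie_lexicographic(self):
        X = self.frame(np.array([[-1.0], [1.0], [50.0], [52.0]]))
        m = kmeans(X, 2, seed=0, transform="none", scale=False)
        low = m.labels_[0]
        assert representative_patient(m, X, low).patient_id == "P000"

    def test_matches_bruteforce_argmin(self):
        rng = np.random.default_rng(14)
        X = self.frame(rng.normal(size=(100, 5)))
        m = kmeans(X, 3, seed=0, transform="none", scale=False)
        for cl in range(3):
            rep = representative_patient(m, X, cl)
            members = np.flatnonzero(m.labels_ == cl)
            d = ((X.to_numpy()[members] - m.cluster_centers_[cl]) ** 2).sum(1)
            assert rep.patient_id == X.index[members[d.argmin()]]


class TestLabelClusters:
    @staticmethod
    def cohort(onsets=(28, 35, 44)):
        """Five hand-built clusters: three decay (given onsets), preventive, zero."""
        rows, assign = [], {}
        pid = 0
        for cl, onset in enumerate(onsets):
            for _ in range(6):
                p = f"P{pid:03d}"; pid += 1
                rows += [(p, onset, VisitCategory.T_OR, 3000.0),
                         (p, min(onset + 3, 60), VisitCategory.T_NOR, 500.0)]
                assign[p] = cl
        for _ in range(8):
            p = f"P{pid:03d}"; pid += 1
            rows += [(p, m, VisitCategory.PREVENTIVE, 50.0) for m in (25, 31, 37)]
            assign[p] = 3
        for _ in range(8):
            p = f"P{pid:03d}"; pid += 1
            assign[p] = 4
        visits = make_visits(rows)
        return pd.Series(assign, name="cluster").rename_axis("patient_id"), visits

    def test_planted_structure_labeled_correctly(self):
        assign, visits = self.cohort()
        labels = label_clusters(assign, visits)
        assert labels == {0: SubgroupLabel.EARLY_ONSET, 1: SubgroupLabel.MID_ONSET,
                          2: SubgroupLabel.LATE_ONSET, 3: SubgroupLabel.PREVENTIVE,
                          4: SubgroupLabel.ZERO_UTIL}

    def test_wrong_k_rejected(self):
        assign, visits = self.cohort()
        with pytest.raises(ValueError, match="k=5"):
            label_clusters(assign[assign != 4], visits)

    def test_two_preventive_like_clusters_rejected(self):
        assign, visits = self.cohort()
        # strip T_OR evidence from one decay cluster -> two no-T_OR clusters
        drop = assign.index[assign == 0]
        broken = visits[~((visits.patient_id.isin(drop)) & (visits.category == VisitCategory.T_OR))]
        with pytest.raises(ValueError, match="preventive-like"):
            label_clusters(assign, broken)

    def test_end_to_end_recovery_on_synthetic_cohort(self, small_analysis, small_cohort):
        """Pipeline labels agree with the generator's planted subgroups."""
        _, _, truth = small_cohort
        got = small_analysis.labels_by_patient.map(lambda l: l.value)
        planted = truth.set_index("patient_id").loc[got.index, "subgroup"]
        assert adjusted_rand_score(planted, got) > 0.9
        assert (planted == got).mean() > 0.95
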