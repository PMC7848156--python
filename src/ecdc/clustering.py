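"""k-means clustering of cost-curve vectors, k selection, quality scoring,
representative patients, and subgroup labeling.

The clusterer is :class:`TrajectoryKMeans`, a scikit-learn-style estimator
running Lloyd's algorithm with k-means++ seeding and ``n_init`` restarts on
Euclidean distances.  By default the raw dollar curves are passed through
``log1p`` and per-feature standardization before clustering (see the methods
note: raw-dollar distances are dominated by the heavy-tailed cost scale and
cannot separate utilization patterns; the transform is a documented choice
of this package).

Cluster quality is scored with the silhouette score (in [-1, 1]) and the
Calinski-Harabasz ratio (reported both raw and normalized to [0, 1) as
raw / (1 + raw)), each compared against a uniform random-assignment
baseline.  For the five-cluster solution, clusters are mapped bijectively to
the subgroup labels: zero utilization, regular preventive care, and early-,
mid-, late-onset of decay ordered by the median age at the first treatment
visit with operating-room use (T+OR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import calinski_harabasz_score, silhouette_score
from sklearn.utils.validation import check_is_fitted

from .visit_categorizer import VisitCategory

logger = logging.getLogger(__name__)

#: Finite stand-in for an infinite Calinski-Harabasz ratio (zero
#: within-cluster dispersion).
CH_SENTINEL = 1e12


class SubgroupLabel(Enum):
    EARLY_ONSET = "early_onset"
    MID_ONSET = "mid_onset"
    LATE_ONSET = "late_onset"
    PREVENTIVE = "preventive"
    ZERO_UTIL = "zero_util"


#: Presentation order for tables.
LABEL_ORDER = [
    SubgroupLabel.EARLY_ONSET,
    SubgroupLabel.MID_ONSET,
    SubgroupLabel.LATE_ONSET,
    SubgroupLabel.PREVENTIVE,
    SubgroupLabel.ZERO_UTIL,
]


@dataclass
class ClusterQuality:
    silhouette: float
    calinski_harabasz: float
    normalized_ch: float


@dataclass
class RepresentativePatient:
    cluster: int
    patient_id: str
    first_tor_age_months: int | None = None


# ---------------------------------------------------------------------------
# Lloyd's algorithm


def _sqdist(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    d2 = (X * X).sum(1)[:, None] - 2.0 * X @ C.T + (C * C).sum(1)[None, :]
    return np.maximum(d2, 0.0)


def _kpp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: centers drawn proportional to squared distance."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(1)
    for j in range(1, k):
        total = d2.sum()
        idx = rng.integers(n) if total <= 0 else rng.choice(n, p=d2 / total)
        centers[j] = X[idx]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(1))
    return centers


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int = 300):
    """One Lloyd run.  Returns (centers, labels, inertia, history, n_iter).

    ``history`` is the inertia after each assignment step; it is checked to
    be non-increasing (a defining property of Lloyd iterations).
    """
    n, k = X.shape[0], centers.shape[0]
    centers = centers.copy()
    labels = np.full(n, -1)
    history: list[float] = []
    for it in range(max_iter):
        D = _sqdist(X, centers)
        new_labels = D.argmin(1)
        # Re-seed empty clusters at the currently worst-fit point.
        for j in range(k):
            if not (new_labels == j).any():
                far = D[np.arange(n), new_labels].argmax()
                centers[j] = X[far]
                D[:, j] = ((X - centers[j]) ** 2).sum(1)
                new_labels = D.argmin(1)
        inertia = float(D[np.arange(n), new_labels].sum())
        if history and inertia > history[-1] * (1 + 1e-9) + 1e-9:
            raise AssertionError("Lloyd inertia increased between iterations")
        history.append(inertia)
        if (new_labels == labels).all():
            break
        labels = new_labels
        for j in range(k):
            centers[j] = X[labels == j].mean(0)
    return centers, labels, history[-1], history, it + 1


class TrajectoryKMeans(BaseEstimator, ClusterMixin):
    """k-means over cumulative cost-curve vectors (Euclidean distance).

    Parameters
    ----------
    n_clusters : int, default 5
        Number of clusters k (2 <= k <= n samples).
    n_init : int, default 10
        Number of k-means++ restarts; the solution with the lowest inertia
        wins.
    max_iter : int, default 300
        Lloyd iteration cap per restart (runs stop earlier when assignments
        are stable).
    random_state : int or None
        Seed; a fixed seed makes the fit fully deterministic.
    transform : {"log1p", "none"}, default "log1p"
        Element-wise compression applied to the dollar curves before
        clustering.
    scale : bool, default True
        Standardize each feature (zero mean, unit variance; constant
        features are left untouched) after the transform.

    Attributes
    ----------
    cluster_centers_ : (k, p) array, in the transformed clustering space.
    labels_ : (n,) cluster index per fitted sample.
    inertia_ : sum of squared distances to assigned centers.
    inertia_history_ : per-iteration inertia of the winning restart
        (non-increasing).
    patient_ids_ : row index of the fitted frame, if X was a DataFrame.
    """

    def __init__(self, n_clusters=5, n_init=10, max_iter=300, random_state=None,
                 transform="log1p", scale=True):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state
        self.transform = transform
        self.scale = scale

    # -- feature-space preparation -------------------------------------
    def _compress(self, X: np.ndarray) -> np.ndarray:
        if self.transform == "log1p":
            return np.log1p(X)
        if self.transform in (None, "none"):
            return np.asarray(X, dtype=float)
        raise ValueError(f"unknown transform {self.transform!r}")

    def _prepare_fit(self, X: np.ndarray) -> np.ndarray:
        Z = self._compress(X)
        if self.scale:
            self.scale_mean_ = Z.mean(0)
            sd = Z.std(0)
            self.scale_std_ = np.where(sd > 0, sd, 1.0)
        else:
            self.scale_mean_ = np.zeros(Z.shape[1])
            self.scale_std_ = np.ones(Z.shape[1])
        return (Z - self.scale_mean_) / self.scale_std_

    def _prepare_apply(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (self._compress(X) - self.scale_mean_) / self.scale_std_

    # -- estimator API -------------------------------------------------
    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            self.patient_ids_ = list(X.index)
            Xa = X.to_numpy(dtype=float)
        else:
            self.patient_ids_ = None
            Xa = np.asarray(X, dtype=float)
        n = Xa.shape[0]
        k = int(self.n_clusters)
        if k < 2 or k > n:
            raise ValueError(f"n_clusters must be in [2, n={n}], got {k}")
        if len(np.unique(Xa, axis=0)) < k:
            raise ValueError("need at least n_clusters distinct vectors")
        Z = self._prepare_fit(Xa)
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(int(self.n_init)):
            init = _kpp_init(Z, k, rng)
            centers, labels, inertia, history, n_iter = _lloyd(Z, init, self.max_iter)
            if best is None or inertia < best[2]:
                best = (centers, labels, inertia, history, n_iter)
        self.cluster_centers_, self.labels_, self.inertia_, self.inertia_history_, self.n_iter_ = best
        self.n_features_in_ = Xa.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        Z = self._prepare_apply(X)
        return _sqdist(Z, self.cluster_centers_).argmin(1)

    def assignments(self) -> pd.Series:
        """Cluster index per patient_id (requires a DataFrame fit)."""
        check_is_fitted(self, "labels_")
        if self.patient_ids_ is None:
            raise ValueError("fit with a DataFrame to get patient assignments")
        return pd.Series(self.labels_, index=pd.Index(self.patient_ids_, name="patient_id"), name="cluster")


def kmeans(vectors, k: int, seed: int | None = None, n_init: int = 10, **kwargs) -> TrajectoryKMeans:
    """Thin functional wrapper: fit a :class:`TrajectoryKMeans` and return it."""
    return TrajectoryKMeans(n_clusters=k, n_init=n_init, random_state=seed, **kwargs).fit(vectors)


# ---------------------------------------------------------------------------
# k selection


@dataclass
class ElbowResult:
    k: int
    ks: list[int]
    inertias: list[float]
    curvatures: dict[int, float]


def elbow_select_k(vectors, k_range=range(2, 9), seed: int | None = None,
                   n_init: int = 10, **kwargs) -> ElbowResult:
    """Select k at the knee of the inertia-vs-k curve.

    The knee is automated as the k maximizing the discrete curvature of the
    *log* inertia curve, ``log I(k-1) - 2 log I(k) + log I(k+1)``; working on
    the log curve makes the criterion scale-free, so a knee is the point
    where the relative improvement collapses rather than the largest
    absolute drop (which, with clusters of very different spread, always
    sits at the smallest k).  Endpoint k values, which have no curvature,
    are eligible only if the curve is flat (degenerate data), in which case
    the smallest k is returned.  The full inertia curve is logged and
    returned so the selection is auditable.
    """
    ks = sorted(int(k) for k in k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values")
    Xa = vectors.to_numpy(dtype=float) if isinstance(vectors, pd.DataFrame) else np.asarray(vectors, float)
    if (Xa == Xa[0]).all():
        # degenerate: every point identical, inertia flat at zero
        logger.info("elbow: all points identical -> k=%d", ks[0])
        return ElbowResult(ks[0], ks, [0.0] * len(ks), {})
    inertias = []
    for k in ks:
        est = TrajectoryKMeans(n_clusters=k, n_init=n_init, random_state=seed, **kwargs).fit(vectors)
        inertias.append(est.inertia_)
    eps = 1e-12
    if max(inertias) - min(inertias) <= eps * (1 + abs(max(inertias))):
        logger.info("elbow: flat inertia curve %s -> k=%d", inertias, ks[0])
        return ElbowResult(ks[0], ks, inertias, {})
    # anchor the curve with the analytic k=1 inertia (total dispersion in the
    # clustering space) so the smallest fitted k also has a curvature
    if ks[0] == 2:
        probe = TrajectoryKMeans(n_clusters=2, random_state=seed, **kwargs)
        Z = probe._prepare_fit(Xa)
        ext_ks = [1] + ks
        ext_inertias = [float(((Z - Z.mean(0)) ** 2).sum())] + inertias
    else:
        ext_ks, ext_inertias = ks, inertias
    logI = np.log(np.maximum(ext_inertias, eps))
    curv = {ext_ks[i]: float(logI[i - 1] - 2 * logI[i] + logI[i + 1])
            for i in range(1, len(ext_ks) - 1)
            if ext_ks[i] - ext_ks[i - 1] == 1 and ext_ks[i + 1] - ext_ks[i] == 1}
    k_sel = min(curv, key=lambda k: (-curv[k], k))
    logger.info("elbow: inertia curve %s, curvatures %s -> k=%d",
                dict(zip(ks, inertias)), curv, k_sel)
    return ElbowResult(k_sel, ks, inertias, curv)


# ---------------------------------------------------------------------------
# Quality scores


def _check_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("quality scores need at least 2 nonempty clusters")
    return labels


def silhouette(vectors, labels, sample_size: int | None = None, seed: int | None = None) -> float:
    """Mean silhouette coefficient, in [-1, 1] (singletons contribute 0)."""
    X = np.asarray(vectors, dtype=float)
    labels = _check_labels(labels)
    return float(silhouette_score(X, labels, sample_size=sample_size, random_state=seed))


def calinski_harabasz(vectors, labels) -> tuple[float, float]:
    """Calinski-Harabasz variance-ratio score, raw and normalized.

    Raw: between-cluster dispersion / (k-1) over within-cluster dispersion /
    (n-k).  A zero within-dispersion (perfect separation) is reported as the
    finite sentinel :data:`CH_SENTINEL`.  Normalized: raw / (1 + raw), in
    [0, 1).
    """
    X = np.asarray(vectors, dtype=float)
    labels = _check_labels(labels)
    intra = sum(float(((X[labels == c] - X[labels == c].mean(0)) ** 2).sum())
                for c in np.unique(labels))
    if intra <= 1e-12:
        return CH_SENTINEL, CH_SENTINEL / (1.0 + CH_SENTINEL)
    raw = float(calinski_harabasz_score(X, labels))
    if not np.isfinite(raw) or raw > CH_SENTINEL:
        raw = CH_SENTINEL
    return raw, raw / (1.0 + raw)


def random_clustering_baseline(vectors, k: int, seed: int | None = None, reps: int = 10) -> ClusterQuality:
    """Quality of uniform random assignments into k clusters, averaged over reps."""
    X = np.asarray(vectors, dtype=float)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    sil, ch, nch = [], [], []
    for _ in range(reps):
        labels = rng.integers(0, k, size=n)
        while len(np.unique(labels)) < 2:  # pragma: no cover - vanishing probability
            labels = rng.integers(0, k, size=n)
        sil.append(silhouette(X, labels, sample_size=min(n, 2000), seed=int(rng.integers(2**31))))
        r, nr = calinski_harabasz(X, labels)
        ch.append(r)
        nch.append(nr)
    return ClusterQuality(float(np.mean(sil)), float(np.mean(ch)), float(np.mean(nch)))


# ---------------------------------------------------------------------------
# Representatives and labeling


def representative_patient(model: TrajectoryKMeans, vectors: pd.DataFrame, cluster: int) -> RepresentativePatient:
    """Cluster member nearest its center (ties -> smallest patient_id)."""
    check_is_fitted(model, "cluster_centers_")
    assign = model.assignments()
    members = assign.index[assign.to_numpy() == cluster]
    if len(members) == 0:
        raise ValueError(f"cluster {cluster} is empty")
    Z = model._prepare_apply(vectors.loc[members].to_numpy(dtype=float))
    d2 = _sqdist(Z, model.cluster_centers_[[cluster]])[:, 0]
    order = sorted(range(len(members)), key=lambda i: (d2[i], members[i]))
    return RepresentativePatient(cluster, members[order[0]])


def patient_visit_stats(visits: pd.DataFrame, patient_ids) -> pd.DataFrame:
    """Per-patient window summaries used by labeling and tables.

    Columns: total_cost, n_visits, has_tor, first_tor_age (NaN when the
    patient never had a T+OR visit).
    """
    idx = pd.Index(patient_ids, name="patient_id")
    out = pd.DataFrame(index=idx, data={"total_cost": 0.0, "n_visits": 0, "has_tor": False,
                                        "first_tor_age": np.nan})
    if len(visits):
        g = visits.groupby("patient_id")
        out.loc[g.size().index, "n_visits"] = g.size()
        out.loc[g["cost"].sum().index, "total_cost"] = g["cost"].sum()
        tor = visits[visits["category"] == VisitCategory.T_OR]
        if len(tor):
            first = tor.groupby("patient_id")["age_months"].min()
            out.loc[first.index, "has_tor"] = True
            out.loc[first.index, "first_tor_age"] = first
    return out


def label_clusters(assignments: pd.Series, visits: pd.DataFrame) -> dict[int, SubgroupLabel]:
    """Map the five clusters bijectively to subgroup labels.

    Rules (in order, all on per-cluster medians for robustness):

    1. the cluster with the smallest median total cost, which must also have
       a zero median visit count, is ZERO_UTIL;
    2. among the rest, the unique cluster whose median patient has no T+OR
       visit is PREVENTIVE;
    3. the remaining three clusters, ordered by median age at the first
       T+OR visit, are EARLY_ONSET < MID_ONSET < LATE_ONSET.

    Raises ``ValueError`` with diagnostics when k != 5 or the rules do not
    produce a bijection.
    """
    clusters = sorted(assignments.unique())
    if len(clusters) != 5:
        raise ValueError(f"subgroup labels are defined for k=5, got k={len(clusters)}")
    stats = patient_visit_stats(visits, assignments.index)
    per = pd.DataFrame(
        {
            "median_cost": stats.groupby(assignments)["total_cost"].median(),
            "median_visits": stats.groupby(assignments)["n_visits"].median(),
            "tor_share": stats.groupby(assignments)["has_tor"].mean(),
            "median_first_tor": stats[stats["has_tor"]].groupby(assignments)["first_tor_age"].median(),
        }
    )

    zero = per["median_cost"].idxmin()
    if per.loc[zero, "median_visits"] != 0:
        raise ValueError(f"lowest-cost cluster has nonzero median visit count:\n{per}")
    rest = per.drop(index=zero)
    no_tor = rest.index[rest["tor_share"] < 0.5]
    if len(no_tor) != 1:
        raise ValueError(f"expected exactly one preventive-like cluster, found {list(no_tor)}:\n{per}")
    preventive = no_tor[0]
    decay = rest.drop(index=preventive)
    if decay["median_first_tor"].isna().any():
        raise ValueError(f"decay-like cluster without T+OR visits:\n{per}")
    ordered = decay["median_first_tor"].sort_values().index
    mapping = {zero: SubgroupLabel.ZERO_UTIL, preventive: SubgroupLabel.PREVENTIVE}
    for cl, lab in zip(ordered, [SubgroupLabel.EARLY_ONSET, SubgroupLabel.MID_ONSET, SubgroupLabel.LATE_ONSET]):
        mapping[cl] = lab
    if len(set(mapping.values())) != 5:
        raise ValueError(f"labeling is not bijective: {mapping}\n{per}")
    return mapping
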