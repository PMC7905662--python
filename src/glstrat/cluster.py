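"""Feature-resampled consensus clustering with PAM, and Ward grouping.

Patients are clustered by k-medoids (PAM, BUILD + SWAP) on a sample-sample
distance computed from the selected lncRNA features; each of ``n_iter``
iterations resamples a fraction of features, and the consensus matrix records
how often two samples co-cluster.  The number of clusters is guided by the
relative increase ("delta area") of the area under the consensus-value ECDF.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def sample_distance(X: np.ndarray, metric: str = "pearson") -> np.ndarray:
    """Sample-sample distance over rows of X (samples x features).

    ``pearson`` is 1 - Pearson correlation of sample profiles (the expression
    convention); ``euclidean`` is available for raw-score matrices.
    """
    if metric == "pearson":
        c = np.corrcoef(X)
        c = np.clip(np.atleast_2d(c), -1.0, 1.0)
        d = 1.0 - c
    elif metric == "euclidean":
        sq = (X**2).sum(axis=1)
        d = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2.0 * X @ X.T, 0.0))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


# ---------------------------------------------------------------------------
# PAM (k-medoids, BUILD + SWAP)
# ---------------------------------------------------------------------------


def pam(dist: np.ndarray, k: int, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids on a precomputed distance matrix.

    BUILD greedily seeds k medoids; SWAP performs steepest-descent medoid
    exchanges until no swap lowers the total within-cluster distance.  Ties
    are broken by lowest index, so the result is deterministic.
    Returns (medoid indices, labels 0..k-1).
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if not (2 <= k < n):
        raise ValueError(f"need 2 <= k < n; got k={k}, n={n}")

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        nearest = np.minimum(nearest, D[best])

    medoids_arr = np.asarray(sorted(medoids))
    for _ in range(max_iter):
        dm = D[medoids_arr]  # k x n
        order = np.argsort(dm, axis=0, kind="stable")
        near_idx = order[0]
        d1 = dm[near_idx, np.arange(n)]
        d2 = dm[order[1], np.arange(n)]

        best_delta, best_swap = -1e-12, None
        non_medoids = np.setdiff1d(np.arange(n), medoids_arr)
        Dh = D[:, non_medoids]  # n x h candidates as columns
        for mi, m in enumerate(medoids_arr):
            is_near = near_idx == mi
            # candidate h replaces medoid m: each point pays
            #   min(d2, d(h))        if its nearest medoid was m
            #   min(d1, d(h))        otherwise
            new_cost = np.where(
                is_near[:, None],
                np.minimum(d2[:, None], Dh),
                np.minimum(d1[:, None], Dh),
            ).sum(axis=0)
            deltas = new_cost - d1.sum()
            j = int(np.argmin(deltas))
            if deltas[j] < best_delta:
                best_delta = float(deltas[j])
                best_swap = (mi, int(non_medoids[j]))
        if best_swap is None:
            break
        mi, h = best_swap
        medoids_arr[mi] = h
        medoids_arr = np.sort(medoids_arr)
    labels = np.argmin(D[medoids_arr], axis=0)
    labels[medoids_arr] = np.arange(k)  # medoids belong to their own cluster
    return medoids_arr, labels


class PAM(BaseEstimator, ClusterMixin):
    """scikit-learn style k-medoids clusterer.

    ``metric`` may be "precomputed" (X is a distance matrix), "pearson", or
    "euclidean".
    """

    def __init__(self, n_clusters: int = 3, metric: str = "precomputed"):
        self.n_clusters = n_clusters
        self.metric = metric

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        D = X if self.metric == "precomputed" else sample_distance(X, self.metric)
        self.medoid_indices_, self.labels_ = pam(D, self.n_clusters)
        dm = D[self.medoid_indices_]
        self.inertia_ = float(dm[self.labels_, np.arange(len(self.labels_))].sum())
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------


@dataclass
class ConsensusResult:
    k: int
    consensus_matrix: pd.DataFrame
    labels: pd.Series  # 1..k
    cdf_x: np.ndarray
    cdf_y: np.ndarray
    area_under_cdf: float
    n_iterations: int
    feature_fraction: float

    def __post_init__(self) -> None:
        m = self.consensus_matrix.to_numpy()
        assert np.allclose(m, m.T), "consensus matrix must be symmetric"
        assert np.allclose(np.diag(m), 1.0), "consensus diagonal must be 1"
        assert (m >= -1e-12).all() and (m <= 1 + 1e-12).all()


def _consensus_area(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ECDF of upper-triangle consensus values and the area under it on [0,1]."""
    x = np.sort(values)
    y = np.arange(1, len(x) + 1) / len(x)
    # step-function integral over [0, 1]
    xs = np.concatenate([[0.0], x, [1.0]])
    ys = np.concatenate([[0.0], y])
    area = float(np.sum(np.diff(xs) * ys))
    return x, y, area


class ConsensusCluster(BaseEstimator, ClusterMixin):
    """Feature-resampled consensus clustering over a range of k.

    ``fit(X)`` takes a samples x features matrix (the z-scored log2-CPM of the
    selected lncRNAs in the main pipeline).  Each iteration draws
    ``ceil(feature_fraction * n_features)`` features without replacement,
    computes the sample distance on that subset, and runs PAM for each k; the
    consensus matrix is the co-assignment frequency over iterations.  Final
    labels come from average-linkage hierarchical clustering of
    1 - consensus, cut at k.
    """

    def __init__(
        self,
        k_range=(2, 3, 4, 5),
        n_iter: int = 1000,
        feature_fraction: float = 0.95,
        metric: str = "pearson",
        random_state: int = 0,
    ):
        self.k_range = k_range
        self.n_iter = n_iter
        self.feature_fraction = feature_fraction
        self.metric = metric
        self.random_state = random_state

    def fit(self, X, y=None):
        index = X.index if hasattr(X, "index") else pd.RangeIndex(len(X))
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        ks = sorted(self.k_range)
        if p < 2:
            raise ValueError("need at least 2 features")
        if any(k < 2 or k >= n for k in ks):
            raise ValueError("k_range must lie within [2, n_samples - 1]")
        if not 0.0 < self.feature_fraction <= 1.0:
            raise ValueError("feature_fraction must lie in (0, 1]")
        rng = np.random.default_rng(self.random_state)
        n_sub = int(np.ceil(self.feature_fraction * p))
        counts = {k: np.zeros((n, n)) for k in ks}
        for _ in range(self.n_iter):
            cols = rng.choice(p, size=n_sub, replace=False)
            D = sample_distance(X[:, cols], self.metric)
            for k in ks:
                _, lab = pam(D, k)
                same = lab[:, None] == lab[None, :]
                counts[k] += same
        self.results_ = []
        for k in ks:
            cm = counts[k] / self.n_iter
            np.fill_diagonal(cm, 1.0)
            labels = _labels_from_consensus(cm, k)
            tri = cm[np.triu_indices(n, k=1)]
            cx, cy, area = _consensus_area(tri)
            self.results_.append(
                ConsensusResult(
                    k=k,
                    consensus_matrix=pd.DataFrame(cm, index=index, columns=index),
                    labels=pd.Series(labels, index=index, name="cluster"),
                    cdf_x=cx,
                    cdf_y=cy,
                    area_under_cdf=area,
                    n_iterations=self.n_iter,
                    feature_fraction=self.feature_fraction,
                )
            )
        areas, deltas, suggested = consensus_cdf_delta_area(self.results_)
        self.areas_ = areas
        self.deltas_ = deltas
        self.suggested_k_ = suggested
        by_k = {r.k: r for r in self.results_}
        self.labels_ = by_k[suggested].labels.to_numpy() - 1
        return self

    def result_for(self, k: int) -> ConsensusResult:
        for r in self.results_:
            if r.k == k:
                return r
        raise KeyError(k)


def _labels_from_consensus(cm: np.ndarray, k: int) -> np.ndarray:
    d = 1.0 - cm
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust")


def consensus_cluster(
    features: pd.DataFrame,
    k_range=(2, 3, 4, 5),
    n_iter: int = 1000,
    feature_fraction: float = 0.95,
    metric: str = "pearson",
    seed: int = 0,
) -> list[ConsensusResult]:
    """Functional wrapper over :class:`ConsensusCluster`.

    ``features`` is samples x features (e.g. selected lncRNAs).
    """
    est = ConsensusCluster(
        k_range=k_range,
        n_iter=n_iter,
        feature_fraction=feature_fraction,
        metric=metric,
        random_state=seed,
    )
    est.fit(features)
    return est.results_


def consensus_cdf_delta_area(
    results: list[ConsensusResult], elbow_threshold: float = 0.1
) -> tuple[dict[int, float], dict[int, float], int]:
    """Area under the consensus CDF per k, relative delta-area sequence, and
    the suggested k.

    delta(k_min) = A_{k_min}; delta(k) = (A_k - A_{k-1}) / A_{k-1} for larger
    k.  A delta below the elbow threshold marks the first k past the stable
    structure ("no appreciable increase"), so the suggested k is the one just
    before it.  If every increase stays appreciable the consensus never
    plateaus — the signature of unstructured data — and k_min is suggested.
    The full area/delta tables are always returned so callers can override.
    """
    ks = sorted(r.k for r in results)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need results for >= 3 consecutive k")
    areas = {r.k: r.area_under_cdf for r in results}
    deltas: dict[int, float] = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        deltas[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else np.inf
    below = [k for k in ks[1:] if deltas[k] < elbow_threshold]
    if below:
        suggested = max(ks[0], below[0] - 1)
    else:
        suggested = ks[0]
        logger.info("no delta-area plateau found; suggesting k_min")
    return areas, deltas, suggested


# ---------------------------------------------------------------------------
# Ward grouping of immune scores
# ---------------------------------------------------------------------------


def hierarchical_ward(scores: pd.DataFrame, n_groups: int = 2) -> pd.Series:
    """Group samples by Euclidean/Ward agglomeration of score profiles.

    ``scores`` is cell-type x sample.  Groups are relabeled by descending
    mean score, so group 1 is the high-infiltration group.
    """
    X = scores.to_numpy(dtype=float).T  # samples x cell types
    n = X.shape[0]
    if n < 2:
        raise ValueError("need >= 2 samples")
    if np.allclose(X, X[0]):
        warnings.warn("constant score matrix; Ward split is arbitrary but deterministic")
    if n_groups >= n:
        labels = np.arange(1, n + 1)
    else:
        Z = linkage(X, method="ward")
        labels = fcluster(Z, t=n_groups, criterion="maxclust")
    means = {g: X[labels == g].mean() for g in np.unique(labels)}
    order = sorted(means, key=lambda g: -means[g])
    remap = {g: i + 1 for i, g in enumerate(order)}
    return pd.Series(
        [remap[g] for g in labels], index=scores.columns, name="infiltration_group"
    )
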