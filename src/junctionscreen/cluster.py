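"""Phenotypic clustering of candidate Z-score vectors.

Each candidate gene is a 3-vector of median Z-scores (E-cad, Jun-A,
Cyt-A). The clustering pipeline evaluated here is the one an optimized
junction screen settles on: Mahalanobis distances (covariance pooled from
the candidate matrix), a Gaussian similarity s = exp(-d^2 / (2 sigma^2))
with sigma = 1, a mutual k-nearest-neighbour graph with 30 neighbours, the
normalized graph Laplacian, and k-means on the row-normalized bottom-k
eigenvector embedding. K-means and agglomerative clustering on the same
distances are retained as grid alternatives, and the configuration
(method x distance x k over k = 2..12) is selected by silhouette: fewest
negative silhouette values, ties broken by highest mean silhouette, then
smallest k.

Everything here is deterministic under a fixed ``random_state``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)

__all__ = [
    "compute_distance_matrix",
    "similarity_from_distance",
    "mutual_knn_graph",
    "silhouette_samples_from_distances",
    "PhenotypeClustering",
    "ClusterGridSelector",
    "select_model",
]


def _pooled_covariance(X: np.ndarray, ridge_frac: float = 1e-6) -> np.ndarray:
    """Sample covariance of the full matrix with a small ridge.

    The ridge is proportional to each variance (falling back to the mean
    variance for degenerate axes), which keeps Mahalanobis distances
    exactly equivariant under per-axis rescaling.
    """
    cov = np.atleast_2d(np.cov(X, rowvar=False))
    dv = np.diag(cov).copy()
    fallback = dv[dv > 0].mean() if (dv > 0).any() else 1.0
    dv = np.where(dv > 0, dv, fallback)
    return cov + ridge_frac * np.diag(dv)


def compute_distance_matrix(
    X: np.ndarray,
    metric: str = "mahalanobis",
    covariance: np.ndarray | None = None,
    ridge_frac: float = 1e-6,
) -> np.ndarray:
    """Pairwise distances; Mahalanobis whitens by the pooled covariance.

    d_M(x, y) = sqrt((x - y)^T Sigma^-1 (x - y)); Euclidean is the
    Sigma = I special case. A singular covariance is regularized with a
    small ridge and a warning.
    """
    X = np.asarray(X, dtype=float)
    if metric == "euclidean":
        diff = X[:, None, :] - X[None, :, :]
        D = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    elif metric == "mahalanobis":
        cov = np.asarray(covariance, float) if covariance is not None else _pooled_covariance(X, ridge_frac)
        try:
            chol = np.linalg.cholesky(np.linalg.inv(cov))
        except np.linalg.LinAlgError:
            warnings.warn("singular covariance: ridge regularization applied")
            cov = cov + ridge_frac * max(np.trace(cov), 1.0) / cov.shape[0] * np.eye(cov.shape[0])
            chol = np.linalg.cholesky(np.linalg.inv(cov))
        Xw = X @ chol
        diff = Xw[:, None, :] - Xw[None, :, :]
        D = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    else:
        raise ValueError(f"unknown metric: {metric!r}")
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def similarity_from_distance(D: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Gaussian similarity s = exp(-d^2 / (2 sigma^2)), in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return np.exp(-np.square(D) / (2.0 * sigma**2))


def mutual_knn_graph(S: np.ndarray, k: int = 30) -> np.ndarray:
    """Weight matrix of the mutual k-nearest-neighbour graph.

    Edge (i, j) keeps weight S_ij iff j is among i's k most similar
    neighbours AND i is among j's; the diagonal is zero. Ranking ties are
    broken by index (argsort stability), documented behaviour.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    sim = S.copy()
    np.fill_diagonal(sim, -np.inf)
    order = np.argsort(-sim, axis=1, kind="stable")[:, :k]
    knn = np.zeros((n, n), dtype=bool)
    np.put_along_axis(knn, order, True, axis=1)
    mutual = knn & knn.T
    W = np.where(mutual, S, 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def graph_components(W: np.ndarray) -> tuple[int, np.ndarray]:
    return connected_components((W > 0).astype(int), directed=False)


def silhouette_samples_from_distances(
    D: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Per-point silhouette s_i = (b_i - a_i) / max(a_i, b_i).

    a_i is the mean distance to the other members of i's cluster, b_i the
    smallest mean distance to any other cluster. Members of singleton
    clusters get 0 by convention. Requires >= 2 clusters.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    n = D.shape[0]
    # mean distance from every point to every cluster
    M = np.column_stack([D[:, labels == c].mean(axis=1) for c in uniq])
    counts = np.array([(labels == c).sum() for c in uniq])
    own = np.searchsorted(uniq, labels)
    s = np.zeros(n)
    for i in range(n):
        c = own[i]
        if counts[c] == 1:
            continue
        a = M[i, c] * counts[c] / (counts[c] - 1)  # exclude self from own mean
        b = np.min(np.delete(M[i], c))
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel 0..K-1 by decreasing cluster size, ties by smallest member."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    order = sorted(
        uniq,
        key=lambda c: (-(labels == c).sum(), int(np.argmax(labels == c))),
    )
    mapping = {c: i for i, c in enumerate(order)}
    return np.array([mapping[c] for c in labels], dtype=int)


class PhenotypeClustering(BaseEstimator, ClusterMixin):
    """One grid cell of the clustering optimization.

    Parameters
    ----------
    method : 'spectral' | 'hierarchical' | 'kmeans'
    metric : 'mahalanobis' | 'euclidean'
    n_clusters : k
    sigma : similarity bandwidth (spectral; default 1)
    n_neighbors : mutual kNN neighbourhood size (spectral; default 30)
    laplacian : 'sym' (Ng-Jordan-Weiss row-normalized embedding) or 'rw'
    linkage : agglomerative linkage (hierarchical; default 'average')
    n_init : k-means restarts inside spectral / plain k-means
    random_state : seed for k-means

    Attributes (after fit)
    ----------------------
    labels_ : canonical cluster labels (by decreasing size)
    distance_matrix_, affinity_, graph_ : intermediate matrices
    silhouette_values_, mean_silhouette_, n_negative_silhouette_
    n_components_ : connected components of the mutual kNN graph
    """

    def __init__(
        self,
        method: str = "spectral",
        metric: str = "mahalanobis",
        n_clusters: int = 9,
        sigma: float = 1.0,
        n_neighbors: int = 30,
        laplacian: str = "sym",
        linkage: str = "average",
        covariance=None,
        n_init: int = 50,
        random_state: int | None = 0,
    ):
        self.method = method
        self.metric = metric
        self.n_clusters = n_clusters
        self.sigma = sigma
        self.n_neighbors = n_neighbors
        self.laplacian = laplacian
        self.linkage = linkage
        self.covariance = covariance
        self.n_init = n_init
        self.random_state = random_state

    # -- internals -----------------------------------------------------
    def _spectral_labels(self, W: np.ndarray) -> np.ndarray:
        k = self.n_clusters
        n_comp, comp = graph_components(W)
        self.n_components_ = n_comp
        if n_comp > k:
            warnings.warn(
                f"mutual kNN graph has {n_comp} components > k={k}; "
                "each component becomes its own cluster"
            )
            return comp
        d = W.sum(axis=1)
        d_safe = np.where(d > 0, d, 1.0)
        if self.laplacian == "sym":
            Dinv = 1.0 / np.sqrt(d_safe)
            L = np.eye(len(d)) - (Dinv[:, None] * W * Dinv[None, :])
            _, vecs = eigh(L, subset_by_index=[0, k - 1])
            emb = vecs
            norms = np.linalg.norm(emb, axis=1, keepdims=True)
            emb = emb / np.where(norms > 0, norms, 1.0)
        elif self.laplacian == "rw":
            # L_rw eigenvectors via the generalized problem L v = lambda D v
            L = np.diag(d_safe) - W
            _, vecs = eigh(L, np.diag(d_safe), subset_by_index=[0, k - 1])
            emb = vecs
        else:
            raise ValueError(f"unknown laplacian variant: {self.laplacian!r}")
        km = KMeans(
            n_clusters=k, n_init=self.n_init, random_state=self.random_state
        )
        return km.fit_predict(emb)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < self.n_clusters:
            raise ValueError("more clusters requested than data points")
        D = compute_distance_matrix(X, metric=self.metric, covariance=self.covariance)
        self.distance_matrix_ = D
        self.n_components_ = 1

        if self.n_clusters == 1:
            labels = np.zeros(n, dtype=int)
        elif self.method == "spectral":
            S = similarity_from_distance(D, sigma=self.sigma)
            self.affinity_ = S
            k_eff = min(self.n_neighbors, n - 1)
            if k_eff < self.n_neighbors:
                log.info("n_neighbors reduced to %d for n=%d", k_eff, n)
            W = mutual_knn_graph(S, k=k_eff)
            self.graph_ = W
            labels = self._spectral_labels(W)
        elif self.method == "hierarchical":
            Z = scipy_linkage(squareform(D, checks=False), method=self.linkage)
            labels = fcluster(Z, t=self.n_clusters, criterion="maxclust") - 1
        elif self.method == "kmeans":
            # Mahalanobis k-means == Euclidean k-means in whitened space
            if self.metric == "mahalanobis":
                cov = (
                    np.asarray(self.covariance, float)
                    if self.covariance is not None
                    else _pooled_covariance(X)
                )
                Xfit = X @ np.linalg.cholesky(np.linalg.inv(cov))
            else:
                Xfit = X
            km = KMeans(
                n_clusters=self.n_clusters,
                n_init=self.n_init,
                random_state=self.random_state,
            )
            labels = km.fit_predict(Xfit)
        else:
            raise ValueError(f"unknown method: {self.method!r}")

        self.labels_ = _canonical_labels(labels)
        if np.unique(self.labels_).size >= 2:
            s = silhouette_samples_from_distances(D, self.labels_)
            self.silhouette_values_ = s
            self.mean_silhouette_ = float(s.mean())
            self.n_negative_silhouette_ = int((s < 0).sum())
        else:
            self.silhouette_values_ = None
            self.mean_silhouette_ = np.nan
            self.n_negative_silhouette_ = -1
        return self


class ClusterGridSelector(BaseEstimator):
    """Exhaustive method x distance x k grid with silhouette selection.

    Primary criterion: fewest negative silhouette values ("least
    misclassifications"); ties broken by highest mean silhouette, then
    smallest k. ``report_`` holds the full grid, ``best_model_`` the
    refitted winner.
    """

    def __init__(
        self,
        methods=("kmeans", "hierarchical", "spectral"),
        metrics=("euclidean", "mahalanobis"),
        k_values=tuple(range(2, 13)),
        sigma: float = 1.0,
        n_neighbors: int = 30,
        laplacian: str = "sym",
        linkage: str = "average",
        n_init: int = 50,
        random_state: int | None = 0,
    ):
        self.methods = methods
        self.metrics = metrics
        self.k_values = k_values
        self.sigma = sigma
        self.n_neighbors = n_neighbors
        self.laplacian = laplacian
        self.linkage = linkage
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if not (len(self.methods) and len(self.metrics) and len(self.k_values)):
            raise ValueError("empty grid")
        recs, models = [], {}
        for method in self.methods:
            for metric in self.metrics:
                for k in self.k_values:
                    if k > X.shape[0]:
                        continue
                    model = PhenotypeClustering(
                        method=method,
                        metric=metric,
                        n_clusters=k,
                        sigma=self.sigma,
                        n_neighbors=self.n_neighbors,
                        laplacian=self.laplacian,
                        linkage=self.linkage,
                        n_init=self.n_init,
                        random_state=self.random_state,
                    )
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        model.fit(X)
                    key = (method, metric, k)
                    models[key] = model
                    recs.append(
                        {
                            "method": method,
                            "metric": metric,
                            "k": k,
                            "n_clusters_found": int(np.unique(model.labels_).size),
                            "n_negative_silhouette": model.n_negative_silhouette_,
                            "mean_silhouette": model.mean_silhouette_,
                        }
                    )
        report = pd.DataFrame(recs)
        valid = report[report["n_negative_silhouette"] >= 0].copy()
        if valid.empty:
            raise ValueError("no valid grid cell produced >= 2 clusters")
        valid = valid.sort_values(
            by=["n_negative_silhouette", "mean_silhouette", "k", "method", "metric"],
            ascending=[True, False, True, True, True],
            kind="stable",
        )
        best = valid.iloc[0]
        self.report_ = report
        self.best_params_ = {
            "method": best["method"],
            "metric": best["metric"],
            "k": int(best["k"]),
        }
        self.best_model_ = models[(best["method"], best["metric"], int(best["k"]))]
        self.labels_ = self.best_model_.labels_
        return self


def select_model(
    X,
    methods=("kmeans", "hierarchical", "spectral"),
    metrics=("euclidean", "mahalanobis"),
    k_values=tuple(range(2, 13)),
    **kwargs,
) -> ClusterGridSelector:
    """Functional wrapper over :class:`ClusterGridSelector`."""
    return ClusterGridSelector(
        methods=methods, metrics=metrics, k_values=k_values, **kwargs
    ).fit(np.asarray(X, float))
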