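"""Distances, similarity graph, spectral pipeline, silhouettes, selection."""

import numpy as np
import pytest
from scipy.linalg import eigh
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from junctionscreen.cluster import (
    ClusterGridSelector,
    PhenotypeClustering,
    compute_distance_matrix,
    mutual_knn_graph,
    graph_components,
    silhouette_samples_from_distances,
    similarity_from_distance,
)


from _oracles import brute_force_silhouette


class TestDistances:
    def test_identity_covariance_equals_euclidean(self, rng):
        X = rng.normal(size=(20, 3))
        D_m = compute_distance_matrix(X, "mahalanobis", covariance=np.eye(3))
        D_e = compute_distance_matrix(X, "euclidean")
        np.testing.assert_allclose(D_m, D_e, atol=1e-9)

    def test_hand_computed_two_dimensional_case(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0]])
        D = compute_distance_matrix(X, "mahalanobis", covariance=np.diag([4.0, 1.0]))
        assert D[0, 1] == pytest.approx(1.0)

    def test_symmetric_zero_diagonal(self, rng):
        X = rng.normal(size=(15, 3))
        D = compute_distance_matrix(X)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)

    def test_singular_covariance_regularized(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.warns(UserWarning):
            D = compute_distance_matrix(
                X, "mahalanobis", covariance=np.array([[1.0, 1.0], [1.0, 1.0]])
            )
        assert np.isfinite(D).all()

    def test_axis_rescaling_invariance_under_pooled_covariance(self, rng):
        # multiplying one coordinate by 10 leaves Mahalanobis distances intact
        X = rng.normal(size=(30, 3))
        Y = X.copy()
        Y[:, 2] *= 10.0
        np.testing.assert_allclose(
            compute_distance_matrix(X), compute_distance_matrix(Y), atol=1e-8
        )


class TestSimilarity:
    def test_closed_form_values(self):
        D = np.array([[0.0, 2.0], [2.0, 0.0]])
        S = similarity_from_distance(D, sigma=1.0)
        assert S[0, 0] == pytest.approx(1.0)
        assert S[0, 1] == pytest.approx(np.exp(-2.0))

    def test_strictly_monotone_in_distance(self, rng):
        d = np.sort(rng.uniform(0, 5, size=50))
        s = similarity_from_distance(d, sigma=1.0)
        assert (np.diff(s) < 0).all()

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            similarity_from_distance(np.zeros((2, 2)), sigma=0.0)


class TestMutualKnn:
    def test_k_equal_n_minus_one_gives_complete_graph(self, rng):
        X = rng.normal(size=(8, 3))
        S = similarity_from_distance(compute_distance_matrix(X, "euclidean"))
        W = mutual_knn_graph(S, k=7)
        off = W[~np.eye(8, dtype=bool)]
        assert (off > 0).all()

    def test_collinear_points_only_mutual_edges_survive(self):
        # A--B--C with k=1: B's single neighbour is one of A/C, so at most
        # one of (A,B),(B,C) is mutual and (A,C) never appears
        X = np.array([[0.0], [1.0], [2.1]])
        S = similarity_from_distance(compute_distance_matrix(X, "euclidean"))
        W = mutual_knn_graph(S, k=1)
        assert W[0, 2] == 0 and W[2, 0] == 0
        assert (W > 0).sum() == 2  # exactly one undirected edge

    def test_two_blobs_give_two_components(self):
        X = np.vstack([_ring((0, 0), 8), _ring((50, 50), 8)])
        S = similarity_from_distance(compute_distance_matrix(X, "euclidean"))
        n_comp, _ = graph_components(mutual_knn_graph(S, k=2))
        assert n_comp == 2

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            mutual_knn_graph(np.ones((5, 5)), k=5)


class TestSilhouette:
    def test_two_tight_far_pairs_score_high(self):
        X = np.array([[0.0, 0], [0.1, 0], [10.0, 0], [10.1, 0]])
        D = compute_distance_matrix(X, "euclidean")
        s = silhouette_samples_from_distances(D, np.array([0, 0, 1, 1]))
        assert (s > 0.9).all()

    def test_equidistant_point_scores_near_zero(self):
        X = np.array([[0.0], [1.0], [5.0], [9.0], [10.0]])
        D = compute_distance_matrix(X, "euclidean")
        s = silhouette_samples_from_distances(D, np.array([0, 0, 0, 1, 1]))
        assert abs(s[2]) < 0.25

    def test_singleton_cluster_scores_zero(self):
        D = compute_distance_matrix(np.array([[0.0], [1.0], [5.0]]), "euclidean")
        s = silhouette_samples_from_distances(D, np.array([0, 0, 1]))
        assert s[2] == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette_samples_from_distances(np.zeros((3, 3)), np.zeros(3, dtype=int))

    def test_matches_brute_force_oracle_and_sklearn(self):
        for s in range(10):
            r = np.random.default_rng(s)
            n = int(r.integers(10, 60))
            X = r.normal(size=(n, 3))
            labels = r.integers(0, 4, size=n)
            if np.unique(labels).size < 2:
                continue
            D = compute_distance_matrix(X, "euclidean")
            mine = silhouette_samples_from_distances(D, labels)
            np.testing.assert_allclose(mine, brute_force_silhouette(D, labels), atol=1e-12)
            if np.all(np.bincount(labels)[np.unique(labels)] > 1):
                ref = silhouette_samples(D, labels, metric="precomputed")
                np.testing.assert_allclose(mine, ref, atol=1e-8)


def _ring(center, m, radius=0.5):
    """m points evenly spaced on a circle: every kNN relation is mutual."""
    ang = 2 * np.pi * np.arange(m) / m
    return np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
    )


def _blobs(rng, centers, n_per, sd=0.3):
    X, y = [], []
    for i, c in enumerate(centers):
        X.append(rng.normal(c, sd, size=(n_per, len(c))))
        y.extend([i] * n_per)
    return np.vstack(X), np.array(y)


class TestPhenotypeClustering:
    def test_planted_blobs_recovered_by_spectral_mahalanobis(self, screen156):
        from junctionscreen.screen import aggregate_and_select, plate_zscores

        _, table, labels = screen156
        agg, _ = aggregate_and_select(plate_zscores(table))
        m = agg.merge(labels, on="gene")
        X = m[["median_z_ecad", "median_z_juna", "median_z_cyta"]].to_numpy()
        model = PhenotypeClustering(
            method="spectral", metric="mahalanobis", n_clusters=9, random_state=0
        ).fit(X)
        assert adjusted_rand_score(m["cluster"], model.labels_) >= 0.9
        assert model.n_negative_silhouette_ <= 5

    @pytest.mark.parametrize("method", ["kmeans", "hierarchical", "spectral"])
    def test_all_methods_recover_well_separated_blobs(self, method, rng):
        X, y = _blobs(rng, [(0, 0), (8, 0), (0, 8), (8, 8)], 12)
        model = PhenotypeClustering(
            method=method, metric="euclidean", n_clusters=4, random_state=0
        ).fit(X)
        assert adjusted_rand_score(y, model.labels_) == 1.0

    def test_k_equal_one_reports_missing_silhouette(self, rng):
        X = rng.normal(size=(10, 3))
        model = PhenotypeClustering(n_clusters=1, method="kmeans", metric="euclidean").fit(X)
        assert model.silhouette_values_ is None
        assert np.isnan(model.mean_silhouette_)

    def test_duplicate_rows_share_a_label(self, rng):
        X, _ = _blobs(rng, [(0, 0, 0), (10, 0, 0), (0, 10, 0)], 8)
        X[1] = X[0]
        model = PhenotypeClustering(
            method="hierarchical", metric="euclidean", n_clusters=3
        ).fit(X)
        assert model.labels_[0] == model.labels_[1]

    def test_permutation_equivariance(self, rng):
        # the partition is permutation-equivariant; with distinct cluster
        # sizes the canonical numbering matches exactly as well
        X, _ = _blobs(rng, [(0, 0), (10, 0), (0, 10)], 10)
        X = np.vstack([X, rng.normal((0, 0), 0.3, (4, 2))])  # sizes 14/10/10
        perm = rng.permutation(len(X))
        m1 = PhenotypeClustering(method="hierarchical", metric="euclidean", n_clusters=3).fit(X)
        m2 = PhenotypeClustering(method="hierarchical", metric="euclidean", n_clusters=3).fit(X[perm])
        assert adjusted_rand_score(m1.labels_[perm], m2.labels_) == 1.0
        assert m1.labels_[perm][np.argmin(perm)] == m2.labels_[np.argmin(perm)]

    def test_laplacian_spectrum_sanity(self):
        X = np.vstack([_ring((0, 0), 10), _ring((50, 50), 10)])
        S = similarity_from_distance(compute_distance_matrix(X, "euclidean"))
        W = mutual_knn_graph(S, k=2)
        d = W.sum(axis=1)
        d = np.where(d > 0, d, 1.0)
        Dinv = 1.0 / np.sqrt(d)
        L = np.eye(len(d)) - Dinv[:, None] * W * Dinv[None, :]
        vals = eigh(L, eigvals_only=True)
        assert vals.min() >= -1e-8 and vals.max() <= 2 + 1e-8
        n_comp, _ = graph_components(W)
        assert np.sum(vals < 1e-8) == n_comp

    def test_more_components_than_k_warns_and_splits(self):
        X = np.vstack([_ring((0, 0), 5), _ring((100, 0), 5), _ring((0, 100), 5)])
        with pytest.warns(UserWarning):
            model = PhenotypeClustering(
                method="spectral", metric="euclidean", n_clusters=2,
                n_neighbors=2, random_state=0,
            ).fit(X)
        assert np.unique(model.labels_).size == 3


class TestModelSelection:
    def test_planted_k_selected(self, rng):
        X, _ = _blobs(rng, [(0, 0, 0), (9, 0, 0), (0, 9, 0), (0, 0, 9)], 15)
        sel = ClusterGridSelector(
            methods=("kmeans", "hierarchical"),
            metrics=("euclidean",),
            k_values=tuple(range(2, 9)),
            random_state=0,
        ).fit(X)
        assert sel.best_params_["k"] == 4

    def test_selection_deterministic(self, screen156):
        from junctionscreen.screen import aggregate_and_select, plate_zscores

        _, table, _ = screen156
        agg, _ = aggregate_and_select(plate_zscores(table))
        X = agg[["median_z_ecad", "median_z_juna", "median_z_cyta"]].to_numpy()
        sels = [
            ClusterGridSelector(
                methods=("spectral",), metrics=("mahalanobis",), random_state=3
            ).fit(X)
            for _ in range(2)
        ]
        assert sels[0].best_params_ == sels[1].best_params_
        np.testing.assert_array_equal(sels[0].labels_, sels[1].labels_)

    def test_spectral_mahalanobis_beats_euclidean_on_scale_masked_clusters(self):
        # cluster separation lives on two axes while a third carries large
        # shared variance: whitening recovers the structure Euclidean loses
        results = {"euclidean": [], "mahalanobis": []}
        for s in range(3):
            r = np.random.default_rng(s)
            centers = [(0, 0, 0), (4, 0, 0), (0, 4, 0), (4, 4, 0)]
            X, y = [], []
            for i, c in enumerate(centers):
                pts = r.normal(size=(15, 3)) * (0.5, 0.5, 20.0) + c
                X.append(pts)
                y.extend([i] * 15)
            X, y = np.vstack(X), np.array(y)
            for metric in results:
                model = PhenotypeClustering(
                    method="spectral", metric=metric, n_clusters=4,
                    n_neighbors=15, random_state=0,
                ).fit(X)
                results[metric].append(adjusted_rand_score(y, model.labels_))
        assert np.median(results["mahalanobis"]) >= np.median(results["euclidean"])
        assert np.median(results["mahalanobis"]) > 0.8

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            ClusterGridSelector(methods=(), metrics=(), k_values=()).fit(
                rng.normal(size=(10, 3))
            )
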