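"""Clustering algorithms against brute-force oracles, silhouettes by hand,
nearest-centroid assignment, model persistence."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from gdmclust.clustering import (
    ClusterModel,
    InvalidCombinationError,
    assign_nearest_centroid,
    canonical_order,
    hierarchical_fit,
    kmeans_fit,
    kmedoids_fit,
    silhouette_values,
)
from gdmclust.preprocessing import destandardize

from conftest import make_blobs


def brute_force_kmeans_wcss(X: np.ndarray, k: int) -> float:
    """Global WCSS optimum by enumerating every k-labelling (n small)."""
    n = len(X)
    best = np.inf
    for code in range(k**n):
        labels = np.array([(code // k**i) % k for i in range(n)])
        if len(np.unique(labels)) < k:
            continue
        w = 0.0
        for c in range(k):
            pts = X[labels == c]
            w += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, w)
    return float(best)


class TestKMeans:
    def test_k1_centroid_is_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        model, part = kmeans_fit(X, 1, n_starts=3, seed=0, compute_silhouette=False)
        np.testing.assert_allclose(model.centroids[0], X.mean(axis=0))
        assert model.wcss == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())
        assert (part.labels == 1).all()

    def test_two_separated_blobs_recovered_exactly(self):
        X, truth = make_blobs(n_per=40, k=2, separation=12.0, seed=1)
        model, part = kmeans_fit(X, 2, n_starts=5, seed=1)
        same = (part.labels == truth).mean()
        assert same in (0.0, 1.0)  # perfect up to label flip
        for c in (1, 2):
            members = X[part.labels == c]
            np.testing.assert_allclose(model.centroids[c - 1], members.mean(axis=0))

    def test_fixed_8_points_attains_enumerated_optimum(self):
        X = np.array(
            [[0.0, 0.0], [0.5, 1.1], [1.2, 0.3], [0.8, 0.9],
             [5.0, 5.2], [5.5, 4.4], [6.1, 5.8], [4.7, 5.9]]
        )
        model, _ = kmeans_fit(X, 2, n_starts=20, seed=3)
        assert model.wcss == pytest.approx(brute_force_kmeans_wcss(X, 2), rel=1e-9)

    def test_multistart_matches_global_optimum_on_random_instances(self):
        """>= 99/100 random small instances hit the enumerated global WCSS."""
        rng = np.random.default_rng(7)
        hits = 0
        for trial in range(100):
            n = int(rng.integers(6, 11))
            k = int(rng.integers(2, 4))
            X = rng.normal(size=(n, 2))
            model, _ = kmeans_fit(X, k, n_starts=30, seed=trial)
            if model.wcss <= brute_force_kmeans_wcss(X, k) * (1 + 1e-9):
                hits += 1
        assert hits >= 99

    def test_scale_equivariance(self):
        X, _ = make_blobs(n_per=30, k=3, separation=6.0, seed=5)
        _, p1 = kmeans_fit(X, 3, n_starts=10, seed=4, compute_silhouette=False)
        _, p2 = kmeans_fit(X * 3.7, 3, n_starts=10, seed=4, compute_silhouette=False)
        assert (p1.labels == p2.labels).all()

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_fit(np.zeros((3, 2)), 4)


class TestKMedoids:
    def test_k_equals_n_zero_cost(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 2))
        model, part = kmedoids_fit(X, 6, seed=0, compute_silhouette=False)
        assert len(np.unique(part.labels)) == 6
        # every medoid is a data point
        for m in model.medoids:
            assert (np.abs(X - m).sum(axis=1) < 1e-12).any()

    def test_line_points_manhattan_matches_exhaustive_pair_search(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.5], [30.0]])
        D = cdist(X, X, "cityblock")
        best = min(
            D[:, [i, j]].min(axis=1).sum() for i, j in itertools.combinations(range(7), 2)
        )
        model, _ = kmedoids_fit(X, 2, distance="manhattan", seed=0, compute_silhouette=False)
        got = D[:, [np.where((X == m).all(axis=1))[0][0] for m in model.medoids]].min(axis=1).sum()
        assert got == pytest.approx(best)

    def test_duplicate_points_handled(self):
        X = np.array([[0.0], [0.0], [0.0], [5.0], [5.0]])
        model, part = kmedoids_fit(X, 2, seed=0, compute_silhouette=False)
        assert sorted(part.sizes) == [2, 3]

    def test_medoids_euclidean_separates_blobs(self):
        X, truth = make_blobs(n_per=25, k=2, separation=10.0, seed=9)
        _, part = kmedoids_fit(X, 2, seed=1, compute_silhouette=False)
        agree = (part.labels == truth).mean()
        assert agree in (0.0, 1.0)


def brute_force_complete_linkage_heights(X: np.ndarray) -> list[float]:
    """Naive agglomeration oracle: merge heights for complete linkage."""
    clusters = [[i] for i in range(len(X))]
    D = cdist(X, X)
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for a, b in itertools.combinations(range(len(clusters)), 2):
            h = max(D[i, j] for i in clusters[a] for j in clusters[b])
            if h < best[0]:
                best = (h, (a, b))
        h, (a, b) = best
        heights.append(h)
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return heights


class TestHierarchical:
    def test_three_equidistant_points_cut_to_singletons(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        _, part, _ = hierarchical_fit(X, 3)
        assert sorted(part.sizes) == [1, 1, 1]

    def test_cut_at_k1_single_cluster(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        _, part, _ = hierarchical_fit(X, 1, compute_silhouette=False)
        assert (part.labels == 1).all()

    def test_complete_linkage_heights_match_hand_agglomeration(self):
        X = np.array([[0.0, 0.0], [1.0, 0.2], [3.0, 0.1], [7.0, 1.0], [7.5, 0.5]])
        _, _, Z = hierarchical_fit(X, 2)
        np.testing.assert_allclose(
            sorted(Z[:, 2]), sorted(brute_force_complete_linkage_heights(X)), rtol=1e-12
        )
        assert (np.diff(Z[:, 2]) >= -1e-12).all()  # monotone merge heights

    def test_ward_requires_euclidean(self):
        X = np.random.default_rng(1).normal(size=(10, 2))
        with pytest.raises(InvalidCombinationError):
            hierarchical_fit(X, 2, distance="manhattan", linkage="ward.D2")


def hand_silhouettes(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    D = cdist(X, X)
    out = np.empty(len(X))
    for i in range(len(X)):
        own = (labels == labels[i]) & (np.arange(len(X)) != i)
        if not own.any():
            out[i] = 0.0
            continue
        a = D[i, own].mean()
        b = min(D[i, labels == c].mean() for c in np.unique(labels) if c != labels[i])
        out[i] = (b - a) / max(a, b)
    return out


class TestSilhouette:
    def test_far_blobs_near_one(self):
        X, labels = make_blobs(n_per=20, k=2, separation=30.0, seed=3)
        s = silhouette_values(X, labels)
        assert s.min() > 0.9

    def test_six_points_match_hand_computation(self):
        X = np.array([[0.0, 0], [0.5, 0], [1.0, 1], [5.0, 5], [5.5, 5], [6.0, 6]])
        labels = np.array([1, 1, 1, 2, 2, 2])
        np.testing.assert_allclose(silhouette_values(X, labels), hand_silhouettes(X, labels))

    def test_equidistant_point_scores_zero(self):
        # middle point has a == b exactly
        X = np.array([[0.0], [2.0], [4.0], [6.0]])
        labels = np.array([1, 1, 2, 2])
        s = silhouette_values(X, labels)
        hand = hand_silhouettes(X, labels)
        np.testing.assert_allclose(s, hand)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette_values(np.zeros((4, 2)), np.ones(4))


class TestAssignment:
    def test_destandardised_centroid_assigns_to_its_cluster(self, default_cohort, default_cohort_z):
        Z, scaler = default_cohort_z
        model, part = kmeans_fit(Z, 3, n_starts=10, seed=0, scaling=scaler, variable_set="full5")
        raw = destandardize(model.centroids, scaler)
        table = pd.DataFrame(raw, columns=scaler.variables)
        assigned = assign_nearest_centroid(model, table)
        assert list(assigned.labels) == [1, 2, 3]

    def test_training_labels_are_a_fixed_point(self, default_cohort_z):
        Z, scaler = default_cohort_z
        model, part = kmeans_fit(Z, 3, n_starts=10, seed=0, scaling=scaler, variable_set="full5")
        re = assign_nearest_centroid(model, Z.to_numpy())
        assert (re.labels == part.labels).all()

    def test_assignment_idempotent_and_order_independent(self, default_cohort, default_cohort_z):
        Z, scaler = default_cohort_z
        model, _ = kmeans_fit(Z, 3, n_starts=10, seed=0, scaling=scaler, variable_set="full5")
        once = assign_nearest_centroid(model, default_cohort)
        twice = assign_nearest_centroid(model, default_cohort)
        assert (once.labels == twice.labels).all()
        perm = np.random.default_rng(0).permutation(len(default_cohort))
        shuffled = assign_nearest_centroid(model, default_cohort.iloc[perm].reset_index(drop=True))
        assert (shuffled.labels == once.labels[perm]).all()

    def test_canonical_order_puts_highest_fasting_first(self):
        cents = np.array([[0.1, -1.0, -0.5], [0.0, 1.5, 1.0], [0.2, 0.3, -0.2]])
        order = canonical_order(cents, ["age", "ogtt0", "ogtt60"])
        assert list(cents[order][:, 1]) == sorted(cents[:, 1], reverse=True)


class TestModelPersistence:
    def test_json_round_trip_is_bit_exact(self, default_cohort_z):
        Z, scaler = default_cohort_z
        model, _ = kmeans_fit(Z, 3, n_starts=5, seed=1, scaling=scaler, variable_set="full5")
        text = model.to_json()
        back = ClusterModel.from_json(text)
        assert back.to_json() == text
        np.testing.assert_array_equal(back.centroids, model.centroids)
        assert back.scaling == model.scaling

    def test_round_trip_preserves_assignments(self, default_cohort, default_cohort_z, tmp_path):
        Z, scaler = default_cohort_z
        model, _ = kmeans_fit(Z, 3, n_starts=5, seed=1, scaling=scaler, variable_set="full5")
        path = tmp_path / "model.json"
        model.save(path)
        loaded = ClusterModel.load(path)
        a = assign_nearest_centroid(model, default_cohort).labels
        b = assign_nearest_centroid(loaded, default_cohort).labels
        assert (a == b).all()
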