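"""Candidate clustering algorithms and the nearest-centroid assignment rule.

Three algorithm families operate on the standardised input matrix: k-means
(Euclidean), PAM k-medoids (Euclidean or Manhattan) and agglomerative
hierarchical clustering (complete, average or Ward-D2 linkage).  k-means and
PAM are implemented here with fully specified determinism — k-means++ seeding,
all ties broken to the lowest index, empty k-means clusters repaired by
reseeding to the farthest point, and the Lloyd objective asserted
non-increasing every iteration; the hierarchical merge tree comes from
scipy.  Cluster labels are always relabelled to a canonical clinical order
(descending fasting-glucose centroid, then descending 60-minute glucose) so
that "cluster 1/2/3" is comparable across fits, folds and sites.

A fitted :class:`ClusterModel` carries its scaler and centroids and serialises
to JSON bit-exactly, so a stored model suffices to assign new patients without
any training data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import cdist, pdist
from sklearn.metrics import silhouette_samples

from .preprocessing import ScalingParams, standardize_apply

MODEL_FORMAT_VERSION = "1"

#: Priority of variables used to order clusters canonically (descending).
_CANONICAL_PRIORITY = ("ogtt0", "ogtt_mean", "ogtt60", "ogtt120", "bmipg", "age")

_SCIPY_METRIC = {"euclidean": "euclidean", "manhattan": "cityblock"}


class InvalidCombinationError(ValueError):
    """Algorithm/distance/linkage combination is not defined."""


# --------------------------------------------------------------------------- #
# Data containers
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ClusterModel:
    """A fitted clustering model in standardised space.

    ``centroids`` are the assignment centroids (per-cluster member means in
    standardised space; for k-means these are the native centroids).  For
    k-medoids the data-point exemplars are kept separately in ``medoids``.
    ``wcss`` is the total within-cluster sum of squared Euclidean deviations
    from the member means.
    """

    algorithm: str  # kmeans | kmedoids | hierarchical
    distance: str  # euclidean | manhattan
    linkage: str  # complete | average | ward.D2 | none
    k: int
    centroids: np.ndarray  # k x p, standardised space
    scaling: ScalingParams | None
    variable_set: str | None
    seed: int | None
    n_starts: int
    wcss: float
    training_sizes: tuple[int, ...]
    medoids: np.ndarray | None = None
    version: str = MODEL_FORMAT_VERSION

    def to_json(self) -> str:
        d = {
            "format_version": self.version,
            "algorithm": self.algorithm,
            "distance": self.distance,
            "linkage": self.linkage,
            "k": self.k,
            "variable_set": self.variable_set,
            "scaling": self.scaling.to_dict() if self.scaling is not None else None,
            "centroids": [[float(x) for x in row] for row in self.centroids],
            "medoids": None
            if self.medoids is None
            else [[float(x) for x in row] for row in self.medoids],
            "seed": self.seed,
            "n_starts": self.n_starts,
            "wcss": float(self.wcss),
            "training_sizes": list(self.training_sizes),
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ClusterModel":
        d = json.loads(text)
        return cls(
            algorithm=d["algorithm"],
            distance=d["distance"],
            linkage=d["linkage"],
            k=int(d["k"]),
            centroids=np.asarray(d["centroids"], dtype=float),
            scaling=None if d["scaling"] is None else ScalingParams.from_dict(d["scaling"]),
            variable_set=d["variable_set"],
            seed=d["seed"],
            n_starts=int(d["n_starts"]),
            wcss=float(d["wcss"]),
            training_sizes=tuple(int(x) for x in d["training_sizes"]),
            medoids=None if d.get("medoids") is None else np.asarray(d["medoids"], dtype=float),
            version=d.get("format_version", MODEL_FORMAT_VERSION),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ClusterModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(fh.read())


@dataclass
class Partition:
    """Cluster labels (1..k) with silhouettes and per-cluster summaries."""

    labels: np.ndarray
    role: str  # C_training | C_test_estimated | C_test_reference
    k: int
    sizes: tuple[int, ...] = ()
    silhouette: np.ndarray | None = None
    cluster_mean_silhouette: tuple[float, ...] | None = None
    index: np.ndarray | None = None  # row identifiers of the clustered rows

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not self.sizes:
            self.sizes = tuple(int((self.labels == c).sum()) for c in range(1, self.k + 1))

    @property
    def mean_silhouette(self) -> float | None:
        if self.silhouette is None:
            return None
        return float(np.mean(self.silhouette))


# --------------------------------------------------------------------------- #
# Shared helpers
# --------------------------------------------------------------------------- #


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


def canonical_order(centroids: np.ndarray, variables: list[str] | None) -> np.ndarray:
    """Order of cluster indices sorting centroids by the canonical clinical rule.

    With named variables, clusters sort by descending fasting glucose (or mean
    OGTT when fasting is absent), then by each further glucose/BMI/age column;
    this reproduces the published numbering (1 = hyperglycaemic-obese,
    2 = elevated fasting, 3 = post-load).  Unnamed matrices sort by descending
    centroid coordinates left to right — arbitrary but deterministic.
    """
    centroids = np.asarray(centroids, dtype=float)
    if variables:
        cols = [variables.index(v) for v in _CANONICAL_PRIORITY if v in variables]
        cols += [j for j in range(centroids.shape[1]) if j not in cols]
    else:
        cols = list(range(centroids.shape[1]))
    keys = [centroids[:, j] for j in reversed(cols)]
    # lexsort is ascending; negate for descending priority order
    return np.lexsort([-k for k in keys])


def _relabel(labels0: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Map 0-based labels through ``order`` to canonical 1-based labels."""
    inverse = np.empty(len(order), dtype=int)
    inverse[order] = np.arange(len(order))
    return inverse[labels0] + 1


def _member_means(X: np.ndarray, labels0: np.ndarray, k: int) -> np.ndarray:
    return np.vstack([X[labels0 == c].mean(axis=0) for c in range(k)])


def _wcss(X: np.ndarray, labels0: np.ndarray, k: int) -> float:
    total = 0.0
    for c in range(k):
        pts = X[labels0 == c]
        if len(pts):
            total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def silhouette_values(X, labels, *, metric: str = "euclidean", precomputed: bool = False):
    """Per-sample silhouettes ``s(i) = (b - a)/max(a, b)``; singletons get 0.

    ``X`` is either a data matrix or, with ``precomputed=True``, a square
    distance matrix.  Requires at least two non-empty clusters.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    M, _ = _as_matrix(X)
    if precomputed:
        return silhouette_samples(M, labels, metric="precomputed")
    return silhouette_samples(M, labels, metric=_SCIPY_METRIC[metric])


def _finalize(
    X: np.ndarray,
    variables: list[str] | None,
    labels0: np.ndarray,
    k: int,
    *,
    algorithm: str,
    distance: str,
    linkage: str,
    scaling: ScalingParams | None,
    variable_set: str | None,
    seed: int | None,
    n_starts: int,
    medoid_idx: np.ndarray | None = None,
    compute_silhouette: bool = True,
    index=None,
) -> tuple[ClusterModel, Partition]:
    """Canonical relabel + package model and training partition."""
    if variables is None and scaling is not None:
        variables = list(scaling.variables)
    means = _member_means(X, labels0, k)
    order = canonical_order(means, variables)
    labels = _relabel(labels0, order)
    centroids = means[order]
    medoids = X[medoid_idx[order]] if medoid_idx is not None else None
    wcss = _wcss(X, labels0, k)
    sizes = tuple(int((labels == c).sum()) for c in range(1, k + 1))
    model = ClusterModel(
        algorithm=algorithm,
        distance=distance,
        linkage=linkage,
        k=k,
        centroids=centroids,
        scaling=scaling,
        variable_set=variable_set,
        seed=seed,
        n_starts=n_starts,
        wcss=wcss,
        training_sizes=sizes,
        medoids=medoids,
    )
    sil = None
    cluster_sil = None
    if compute_silhouette and k >= 2 and len(X) > k:
        sil = silhouette_values(X, labels, metric=distance)
        cluster_sil = tuple(float(sil[labels == c].mean()) for c in range(1, k + 1))
    part = Partition(
        labels=labels,
        role="C_training",
        k=k,
        sizes=sizes,
        silhouette=sil,
        cluster_mean_silhouette=cluster_sil,
        index=index,
    )
    return model, part


# --------------------------------------------------------------------------- #
# k-means (Lloyd, k-means++ seeding, multi-start)
# --------------------------------------------------------------------------- #


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(X)
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = X[rng.integers(n)]
            continue
        probs = d2 / total
        centers[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    *,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One Lloyd run from a k-means++ start.  Returns (labels0, centers, wcss)."""
    centers = _kmeanspp_init(X, k, rng)
    labels = None
    prev_obj = np.inf
    for _ in range(max_iter):
        d2 = cdist(X, centers, metric="sqeuclidean")
        new_labels = d2.argmin(axis=1)  # argmin takes the first (lowest) index on ties
        # repair empty clusters: reseed to the point farthest from its centroid
        for c in range(k):
            if not (new_labels == c).any():
                far = d2[np.arange(len(X)), new_labels].argmax()
                centers[c] = X[far]
                d2[:, c] = ((X - centers[c]) ** 2).sum(axis=1)
                new_labels = d2.argmin(axis=1)
        obj = float(d2[np.arange(len(X)), new_labels].sum())
        # Lloyd's objective is non-increasing; violation indicates a defect
        assert obj <= prev_obj + 1e-8 * max(1.0, abs(prev_obj)), "k-means objective increased"
        prev_obj = obj
        new_centers = np.vstack([X[new_labels == c].mean(axis=0) for c in range(k)])
        shift = float(np.abs(new_centers - centers).max())
        stable = labels is not None and np.array_equal(new_labels, labels)
        centers, labels = new_centers, new_labels
        if stable or shift < tol:
            break
    d2 = cdist(X, centers, metric="sqeuclidean")
    labels = d2.argmin(axis=1)
    wcss = float(d2[np.arange(len(X)), labels].sum())
    return labels, centers, wcss


def kmeans_fit(
    X,
    k: int,
    n_starts: int = 50,
    seed: int | None = None,
    *,
    scaling: ScalingParams | None = None,
    variable_set: str | None = None,
    compute_silhouette: bool = True,
    index=None,
) -> tuple[ClusterModel, Partition]:
    """Multi-start Lloyd k-means with Euclidean distance.

    The best of ``n_starts`` k-means++ restarts by WCSS is kept and relabelled
    to canonical order.  ``X`` is a standardised matrix (array or DataFrame).
    """
    M, variables = _as_matrix(X)
    n = len(M)
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_starts)):
        labels0, centers, wcss = _lloyd(M, k, rng)
        if best is None or wcss < best[2]:
            best = (labels0, centers, wcss)
    labels0, _, _ = best
    return _finalize(
        M,
        variables,
        labels0,
        k,
        algorithm="kmeans",
        distance="euclidean",
        linkage="none",
        scaling=scaling,
        variable_set=variable_set,
        seed=seed,
        n_starts=n_starts,
        compute_silhouette=compute_silhouette,
        index=index,
    )


# --------------------------------------------------------------------------- #
# k-medoids (PAM: greedy build + steepest-descent swap)
# --------------------------------------------------------------------------- #


def kmedoids_fit(
    X,
    k: int,
    distance: str = "euclidean",
    seed: int | None = None,
    *,
    scaling: ScalingParams | None = None,
    variable_set: str | None = None,
    compute_silhouette: bool = True,
    index=None,
) -> tuple[ClusterModel, Partition]:
    """PAM k-medoids under Euclidean or Manhattan distance.

    BUILD greedily seeds k medoids minimising total dissimilarity; SWAP
    exchanges (medoid, non-medoid) pairs while the total cost strictly
    decreases.  All ties break to the lowest index.  The model's assignment
    ``centroids`` are member means; the exemplars are kept in ``medoids``.
    """
    if distance not in _SCIPY_METRIC:
        raise InvalidCombinationError(f"unsupported distance {distance!r}")
    M, variables = _as_matrix(X)
    n = len(M)
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    D = cdist(M, M, metric=_SCIPY_METRIC[distance])

    if k == n:  # every point its own medoid, total dissimilarity 0
        return _finalize(
            M, variables, np.arange(n), k,
            algorithm="kmedoids", distance=distance, linkage="none",
            scaling=scaling, variable_set=variable_set, seed=seed, n_starts=1,
            medoid_idx=np.arange(n), compute_silhouette=compute_silhouette, index=index,
        )

    # BUILD
    medoids = [int(D.sum(axis=1).argmin())]
    nearest = D[:, medoids[0]].copy()
    while len(medoids) < k:
        costs = np.minimum(nearest[:, None], D).sum(axis=0)
        costs[medoids] = np.inf
        h = int(costs.argmin())
        medoids.append(h)
        nearest = np.minimum(nearest, D[:, h])

    # SWAP (steepest descent)
    medoid_arr = np.array(sorted(medoids))
    current = float(D[:, medoid_arr].min(axis=1).sum())
    for _ in range(200):
        best_delta, best_swap = -1e-12, None
        for i, m in enumerate(medoid_arr):
            others = np.delete(medoid_arr, i)
            others_min = (
                D[:, others].min(axis=1) if len(others) else np.full(n, np.inf)
            )
            cand = np.setdiff1d(np.arange(n), medoid_arr, assume_unique=False)
            new_costs = np.minimum(others_min[:, None], D[:, cand]).sum(axis=0)
            j = int(new_costs.argmin())
            delta = float(new_costs[j] - current)
            if delta < best_delta:
                best_delta, best_swap = delta, (i, int(cand[j]))
        if best_swap is None:
            break
        i, h = best_swap
        medoid_arr[i] = h
        medoid_arr = np.sort(medoid_arr)
        new_total = float(D[:, medoid_arr].min(axis=1).sum())
        assert new_total <= current + 1e-9, "PAM total dissimilarity increased"
        current = new_total

    labels0 = D[:, medoid_arr].argmin(axis=1)
    return _finalize(
        M,
        variables,
        labels0,
        k,
        algorithm="kmedoids",
        distance=distance,
        linkage="none",
        scaling=scaling,
        variable_set=variable_set,
        seed=seed,
        n_starts=1,
        medoid_idx=medoid_arr,
        compute_silhouette=compute_silhouette,
        index=index,
    )


# --------------------------------------------------------------------------- #
# Agglomerative hierarchical clustering
# --------------------------------------------------------------------------- #

_LINKAGE_MAP = {"complete": "complete", "average": "average", "ward.D2": "ward"}


def hierarchical_fit(
    X,
    k: int,
    distance: str = "euclidean",
    linkage: str = "complete",
    *,
    scaling: ScalingParams | None = None,
    variable_set: str | None = None,
    compute_silhouette: bool = True,
    index=None,
) -> tuple[ClusterModel, Partition, np.ndarray]:
    """Agglomerative clustering cut into k groups.

    Returns ``(model, partition, merge_tree)`` where ``merge_tree`` is the
    scipy linkage matrix.  Ward-D2 requires Euclidean distance.  Assignment
    centroids are the member means of the cut clusters.
    """
    if linkage not in _LINKAGE_MAP:
        raise InvalidCombinationError(f"unsupported linkage {linkage!r}")
    if distance not in _SCIPY_METRIC:
        raise InvalidCombinationError(f"unsupported distance {distance!r}")
    if linkage == "ward.D2" and distance != "euclidean":
        raise InvalidCombinationError("ward.D2 linkage requires Euclidean distance")
    M, variables = _as_matrix(X)
    n = len(M)
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    y = pdist(M, metric=_SCIPY_METRIC[distance])
    Z = scipy_linkage(y, method=_LINKAGE_MAP[linkage])
    labels0 = fcluster(Z, t=k, criterion="maxclust") - 1
    model, part = _finalize(
        M,
        variables,
        labels0,
        k,
        algorithm="hierarchical",
        distance=distance,
        linkage=linkage,
        scaling=scaling,
        variable_set=variable_set,
        seed=None,
        n_starts=1,
        compute_silhouette=compute_silhouette,
        index=index,
    )
    return model, part, Z


# --------------------------------------------------------------------------- #
# Nearest-centroid assignment
# --------------------------------------------------------------------------- #


def assign_nearest_centroid(
    model: ClusterModel, table, *, compute_silhouette: bool = False
) -> Partition:
    """Assign each row to the cluster whose centroid is nearest.

    ``table`` is a raw cohort table (standardised with the model's own scaler)
    or, for a model fitted without a scaler, an already-standardised matrix.
    Distances use the model's metric; ties go to the lowest cluster index.
    Rows with missing inputs are dropped (and logged) by the standardiser.
    """
    if model.scaling is not None and isinstance(table, pd.DataFrame):
        Z = standardize_apply(table, model.scaling)
        idx = Z.index.to_numpy()
        M = Z.to_numpy(dtype=float)
    else:
        M, _ = _as_matrix(table)
        idx = np.arange(len(M))
    d = cdist(M, model.centroids, metric=_SCIPY_METRIC[model.distance])
    labels = d.argmin(axis=1) + 1  # first minimum -> lowest cluster index
    sil = None
    cluster_sil = None
    if compute_silhouette and model.k >= 2 and len(M) > model.k:
        sil = silhouette_values(M, labels, metric=model.distance)
        cluster_sil = tuple(
            float(sil[labels == c].mean()) if (labels == c).any() else 0.0
            for c in range(1, model.k + 1)
        )
    return Partition(
        labels=labels,
        role="C_test_estimated",
        k=model.k,
        sizes=tuple(int((labels == c).sum()) for c in range(1, model.k + 1)),
        silhouette=sil,
        cluster_mean_silhouette=cluster_sil,
        index=idx,
    )


def refit_like(model: ClusterModel, X, seed: int | None = None, **kwargs):
    """Fit the same algorithm configuration as ``model`` on a new matrix."""
    if model.algorithm == "kmeans":
        return kmeans_fit(X, model.k, n_starts=model.n_starts, seed=seed, **kwargs)
    if model.algorithm == "kmedoids":
        return kmedoids_fit(X, model.k, distance=model.distance, seed=seed, **kwargs)
    m, p, _ = hierarchical_fit(X, model.k, distance=model.distance, linkage=model.linkage, **kwargs)
    return m, p
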