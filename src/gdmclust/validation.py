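"""Internal and external validation of clustering solutions.

Internal validation covers clusterwise bootstrap stability (Hennig's scheme:
refit on nonparametric bootstrap resamples and match each original cluster to
the refit cluster with maximal Jaccard overlap on the resampled points) and
twofold cross-validation (fit "partial models" on random halves of the
training set and compare them to the full-data model on input similarity,
result similarity and outcome-significance consistency).  External validation
compares the centroid-transfer partition of a held-out table (C-hat_test)
against a reference partition obtained by refitting the same algorithm on the
test set itself (C_test), reporting per-cluster Jaccard overlap, the adjusted
Rand index, classification metrics and a chi-square comparison of cluster
proportions against training.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .clustering import (
    ClusterModel,
    Partition,
    assign_nearest_centroid,
    refit_like,
)
from .outcomes import ALPHA, OutcomeComparison, compare_outcomes
from .preprocessing import destandardize, standardize_apply, standardize_fit

logger = logging.getLogger(__name__)

JACCARD_THRESHOLD = 0.75  # published stability gate


# --------------------------------------------------------------------------- #
# Partition agreement primitives
# --------------------------------------------------------------------------- #


def jaccard_per_cluster(
    labels_a, labels_b, mapping: dict[int, int] | None = None
) -> dict[int, float]:
    """Per-cluster Jaccard overlap |A ∩ B| / |A ∪ B| over a shared row universe.

    ``mapping`` maps each cluster id of ``labels_a`` to its counterpart in
    ``labels_b`` (identity if omitted).  An empty union yields 0 with a warning.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors must share the same rows")
    clusters = sorted(int(c) for c in np.unique(a))
    mapping = mapping or {c: c for c in clusters}
    out = {}
    for c in clusters:
        in_a = a == c
        in_b = b == mapping[c]
        union = int((in_a | in_b).sum())
        if union == 0:
            logger.warning("cluster %d empty in both partitions; Jaccard set to 0", c)
            out[c] = 0.0
        else:
            out[c] = float((in_a & in_b).sum() / union)
    return out


def match_clusters(labels_ref, labels_est) -> dict[int, int]:
    """Bijective cluster matching maximising total Jaccard agreement.

    Builds the k x k contingency table, derives the pairwise Jaccard overlaps
    ``n_re / (n_r + n_e - n_re)`` and solves the optimal assignment (Hungarian
    method), so the returned bijection dominates every other bijection in
    summed (hence mean) Jaccard.  Requires both partitions to use the same
    number of clusters.
    """
    ref = np.asarray(labels_ref)
    est = np.asarray(labels_est)
    if len(ref) != len(est):
        raise ValueError("label vectors must share the same rows")
    ref_ids = sorted(int(c) for c in np.unique(ref))
    est_ids = sorted(int(c) for c in np.unique(est))
    if len(ref_ids) != len(est_ids):
        raise ValueError(
            f"partitions have different cluster counts ({len(ref_ids)} vs {len(est_ids)})"
        )
    table = np.array(
        [[(np.logical_and(ref == r, est == e)).sum() for e in est_ids] for r in ref_ids],
        dtype=float,
    )
    sizes_r = table.sum(axis=1, keepdims=True)
    sizes_e = table.sum(axis=0, keepdims=True)
    jac = table / (sizes_r + sizes_e - table)
    rows, cols = linear_sum_assignment(-jac)
    return {ref_ids[r]: est_ids[c] for r, c in zip(rows, cols)}


def adjusted_rand(labels_a, labels_b) -> float:
    """Permutation-model adjusted Rand index between two partitions."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors must share the same rows")
    if len(a) < 2:
        raise ValueError("ARI needs at least 2 rows")
    return float(adjusted_rand_score(a, b))


@dataclass
class ClassificationMetrics:
    per_cluster: dict[int, dict[str, float]]  # sensitivity / specificity / f1
    accuracy: float


def classification_metrics(
    labels_ref, labels_est, mapping: dict[int, int] | None = None
) -> ClassificationMetrics:
    """One-vs-rest sensitivity/specificity/F1 per cluster plus total accuracy.

    ``labels_est`` is first mapped onto the reference labelling via
    ``mapping`` (identity if omitted).
    """
    ref = np.asarray(labels_ref)
    est = np.asarray(labels_est)
    clusters = sorted(int(c) for c in np.unique(ref))
    if mapping:
        inverse = {v: k for k, v in mapping.items()}
        est = np.array([inverse.get(int(e), -1) for e in est])
    per = {}
    for c in clusters:
        tp = int(((ref == c) & (est == c)).sum())
        fn = int(((ref == c) & (est != c)).sum())
        fp = int(((ref != c) & (est == c)).sum())
        tn = int(((ref != c) & (est != c)).sum())
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        per[c] = {"sensitivity": sens, "specificity": spec, "f1": f1}
    accuracy = float((ref == est).mean())
    return ClassificationMetrics(per, accuracy)


# --------------------------------------------------------------------------- #
# Bootstrap stability (clusterwise Jaccard)
# --------------------------------------------------------------------------- #


@dataclass
class StabilityReport:
    B: int
    cluster_jaccard: dict[int, float]  # mean over successful replicates
    threshold: float
    passed: dict[int, bool]
    n_failures: int = 0

    @property
    def all_pass(self) -> bool:
        return all(self.passed.values())


def _bootstrap_jaccard_once(
    labels: np.ndarray, boot_labels: np.ndarray, idx: np.ndarray, k: int
) -> dict[int, float]:
    """Clusterwise maximal Jaccard between original clusters and a refit,
    evaluated on the unique points of one bootstrap resample."""
    uniq = np.unique(idx)
    orig = labels[uniq]
    # refit labels per original row: label of the first resample occurrence
    refit_by_row = np.empty(len(labels), dtype=int)
    refit_by_row.fill(-1)
    # later duplicates overwrite; labels agree across duplicates anyway
    refit_by_row[idx] = boot_labels
    new = refit_by_row[uniq]
    out = {}
    for c in range(1, k + 1):
        in_c = orig == c
        if not in_c.any():
            out[c] = 0.0
            continue
        best = 0.0
        for d in np.unique(new):
            in_d = new == d
            j = (in_c & in_d).sum() / (in_c | in_d).sum()
            best = max(best, float(j))
        out[c] = best
    return out


def bootstrap_stability(
    X,
    model: ClusterModel,
    labels,
    B: int = 100,
    seed: int = 0,
    *,
    threshold: float = JACCARD_THRESHOLD,
) -> StabilityReport:
    """Clusterwise bootstrap stability of a fitted solution.

    Draws ``B`` nonparametric bootstrap resamples of the standardised matrix,
    refits the model configuration on each, and matches every original
    cluster to the refit cluster maximising the Jaccard overlap on the
    resample's unique points.  Reports the per-cluster mean Jaccard and the
    gate outcome (mean > threshold).  Refit failures are counted, not fatal.
    """
    if B < 1:
        raise ValueError("B must be positive")
    M = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    sums = {c: 0.0 for c in range(1, model.k + 1)}
    n_ok, n_fail = 0, 0
    for _ in range(B):
        idx = rng.integers(len(M), size=len(M))
        try:
            _, part = refit_like(
                model, M[idx], seed=int(rng.integers(2**31 - 1)), compute_silhouette=False
            )
        except Exception as err:  # refit failures are reported, not fatal
            logger.warning("bootstrap refit failed: %s", err)
            n_fail += 1
            continue
        js = _bootstrap_jaccard_once(labels, part.labels, idx, model.k)
        for c, j in js.items():
            sums[c] += j
        n_ok += 1
    if n_ok == 0:
        raise RuntimeError("all bootstrap refits failed")
    means = {c: sums[c] / n_ok for c in sums}
    return StabilityReport(
        B=B,
        cluster_jaccard=means,
        threshold=threshold,
        passed={c: means[c] > threshold for c in means},
        n_failures=n_fail,
    )


# --------------------------------------------------------------------------- #
# Twofold cross-validation
# --------------------------------------------------------------------------- #


@dataclass
class FoldReport:
    n: int
    scaler_center_delta: tuple[float, ...]
    scaler_scale_delta: tuple[float, ...]
    centroid_distances: tuple[float, ...]  # matched, in the original z-space
    ari: float
    metrics: ClassificationMetrics
    outcome_agreement: dict[str, bool]  # same side of p = 0.05 as the original model
    outcome_p_partial: dict[str, float]
    outcome_p_original: dict[str, float]


@dataclass
class CrossValReport:
    folds: list[FoldReport]

    @property
    def min_ari(self) -> float:
        return min(f.ari for f in self.folds)


def twofold_crossval(
    train: pd.DataFrame,
    model: ClusterModel,
    labels,
    outcome_columns: list[str] | None = None,
    seed: int = 0,
    halves: tuple[np.ndarray, np.ndarray] | None = None,
) -> CrossValReport:
    """Fit partial models on two random halves and compare to the full model.

    Each fold refits the model configuration (own scaler) on one half and
    compares, on that half's rows: the scaler deltas and matched-centroid L2
    distances in the original standardised space (input similarity), ARI and
    per-cluster classification metrics against the original labels (result
    similarity), and — when outcome columns are given — whether each outcome's
    omnibus significance lands on the same side of 0.05 under the partial and
    the original labels (outcome significance consistency).

    ``halves`` overrides the random split (row positions) for reproducible or
    degenerate designs.
    """
    n = len(train)
    labels = np.asarray(labels)
    if halves is None:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        halves = (np.sort(perm[: n // 2]), np.sort(perm[n // 2 :]))
    folds = []
    for fold_idx, rows in enumerate(halves):
        half = train.iloc[rows].reset_index(drop=True)
        if len(half) < model.k:
            raise ValueError(f"fold {fold_idx} too small for k={model.k}")
        scaler = standardize_fit(half, model.variable_set or "full5")
        Zh = standardize_apply(half, scaler)
        pm, part = refit_like(
            model,
            Zh,
            seed=seed + fold_idx + 1,
            scaling=scaler,
            variable_set=model.variable_set,
            compute_silhouette=False,
        )
        orig_half = labels[rows]
        mapping = match_clusters(orig_half, part.labels)
        # input similarity: matched centroids expressed in the original z-space
        raw_centroids = destandardize(pm.centroids, scaler)
        in_orig_space = (raw_centroids - np.asarray(model.scaling.center)) / np.asarray(
            model.scaling.scale
        )
        dists = tuple(
            float(np.linalg.norm(model.centroids[c - 1] - in_orig_space[mapping[c] - 1]))
            for c in sorted(mapping)
        )
        center_delta = tuple(
            float(a - b) for a, b in zip(scaler.center, model.scaling.center)
        )
        scale_delta = tuple(float(a - b) for a, b in zip(scaler.scale, model.scaling.scale))
        ari = adjusted_rand(orig_half, part.labels)
        metrics = classification_metrics(orig_half, part.labels, mapping)
        agreement, p_partial, p_orig = {}, {}, {}
        if outcome_columns:
            inverse = {v: k for k, v in mapping.items()}
            mapped_labels = np.array([inverse[int(c)] for c in part.labels])
            partial_cmp = compare_outcomes(half, mapped_labels, outcome_columns, logistic=False)
            orig_cmp = compare_outcomes(half, orig_half, outcome_columns, logistic=False)
            for name in outcome_columns:
                p1, p0 = partial_cmp[name].p, orig_cmp[name].p
                p_partial[name], p_orig[name] = p1, p0
                agreement[name] = (p1 < ALPHA) == (p0 < ALPHA)
        folds.append(
            FoldReport(
                n=len(half),
                scaler_center_delta=center_delta,
                scaler_scale_delta=scale_delta,
                centroid_distances=dists,
                ari=ari,
                metrics=metrics,
                outcome_agreement=agreement,
                outcome_p_partial=p_partial,
                outcome_p_original=p_orig,
            )
        )
    return CrossValReport(folds)


# --------------------------------------------------------------------------- #
# External validation (centroid transfer vs reference refit)
# --------------------------------------------------------------------------- #


@dataclass
class ExternalValReport:
    mapping: dict[int, int]  # C-hat_test cluster -> C_test cluster
    cluster_jaccard: dict[int, float]
    ari: float
    accuracy: float
    metrics: ClassificationMetrics
    proportion_chi2_p: float | None  # transfer proportions vs training proportions
    estimated: Partition
    reference: Partition | None
    transfer_only: bool = False


def external_validate(
    model: ClusterModel,
    test_table: pd.DataFrame,
    seed: int = 0,
) -> ExternalValReport:
    """Validate a fitted model on an independent test table.

    The estimated partition (C-hat_test) assigns each test row to the nearest
    model centroid under the training scaler; the reference partition (C_test)
    refits the same algorithm on the test set with its own scaler.  After
    optimal cluster matching the report carries per-cluster Jaccard overlap,
    ARI, accuracy and classification metrics between the two partitions, plus
    a chi-square comparison of the transfer cluster proportions against the
    training sizes.  If the reference refit fails, transfer-only results are
    returned with a flag.
    """
    est = assign_nearest_centroid(model, test_table)
    counts_est = np.array(est.sizes)
    prop_p: float | None = None
    if model.training_sizes and sum(model.training_sizes) > 0:
        table = np.vstack([np.asarray(model.training_sizes), counts_est])
        if (table.sum(axis=0) > 0).all():
            prop_p = float(stats.chi2_contingency(table, correction=False)[1])
    try:
        scaler_test = standardize_fit(test_table, model.variable_set or "full5")
        Zt = standardize_apply(test_table, scaler_test)
        _, ref = refit_like(
            model,
            Zt,
            seed=seed,
            scaling=scaler_test,
            variable_set=model.variable_set,
            compute_silhouette=False,
        )
        ref.role = "C_test_reference"
    except Exception as err:
        logger.warning("reference refit failed (%s); transfer-only report", err)
        return ExternalValReport(
            mapping={},
            cluster_jaccard={},
            ari=float("nan"),
            accuracy=float("nan"),
            metrics=ClassificationMetrics({}, float("nan")),
            proportion_chi2_p=prop_p,
            estimated=est,
            reference=None,
            transfer_only=True,
        )
    mapping = match_clusters(est.labels, ref.labels)
    jac = jaccard_per_cluster(est.labels, ref.labels, mapping)
    ari = adjusted_rand(est.labels, ref.labels)
    metrics = classification_metrics(est.labels, ref.labels, mapping)
    return ExternalValReport(
        mapping=mapping,
        cluster_jaccard=jac,
        ari=ari,
        accuracy=metrics.accuracy,
        metrics=metrics,
        proportion_chi2_p=prop_p,
        estimated=est,
        reference=ref,
    )


def all_pair_jaccard_is_optimal(labels_a, labels_b) -> bool:
    """Check that the Hungarian matching dominates every bijection in mean Jaccard."""
    mapping = match_clusters(labels_a, labels_b)
    base = np.mean(list(jaccard_per_cluster(labels_a, labels_b, mapping).values()))
    ids_a = sorted(mapping)
    ids_b = sorted(mapping.values())
    for perm in itertools.permutations(ids_b):
        alt = dict(zip(ids_a, perm))
        val = np.mean(list(jaccard_per_cluster(labels_a, labels_b, alt).values()))
        if val > base + 1e-12:
            return False
    return True
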