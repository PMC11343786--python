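"""Choice of k and algorithm configuration via multiple selection methods
and internal acceptance gates.

Four k-selection methods are computed on the standardised training matrix:
the gap statistic (uniform reference over the PCA-aligned bounding box, 1-SE
rule), silhouette maximisation, a majority vote over seven cluster-validity
indices (Calinski-Harabasz, Davies-Bouldin, Dunn, Hartigan, Krzanowski-Lai,
C-index, silhouette), and the within-cluster-sum-of-squares curve for elbow
inspection.  Candidate solutions — algorithm families in the preference order
k-means, k-medoids, hierarchical; k in the order majority vote then runner-up
— are then screened by three acceptance gates: clusterwise bootstrap Jaccard
above 0.75, non-negative per-cluster mean silhouette, and every input
variable significantly different across the clusters (p < 0.05, routed
through the same normality-based testing scheme used for outcomes).  The
first candidate passing all gates wins; if none does, an explicit
"no acceptable clustering" result is returned rather than an exception.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .clustering import (
    ClusterModel,
    Partition,
    hierarchical_fit,
    kmeans_fit,
    kmedoids_fit,
)
from .outcomes import ALPHA, compare_variable
from .preprocessing import get_variable_set, standardize_apply, standardize_fit
from .validation import JACCARD_THRESHOLD, bootstrap_stability

logger = logging.getLogger(__name__)

DEFAULT_K_RANGE_GAP = range(1, 9)
DEFAULT_K_RANGE = range(2, 9)

#: Candidate algorithm configurations in preference order.
DEFAULT_ROSTER: tuple[tuple[str, str, str], ...] = (
    ("kmeans", "euclidean", "none"),
    ("kmedoids", "euclidean", "none"),
    ("kmedoids", "manhattan", "none"),
    ("hierarchical", "euclidean", "complete"),
    ("hierarchical", "manhattan", "complete"),
    ("hierarchical", "euclidean", "average"),
    ("hierarchical", "manhattan", "average"),
    ("hierarchical", "euclidean", "ward.D2"),
)


def _as_array(X) -> np.ndarray:
    return X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)


def _kmeans_wcss(X: np.ndarray, k: int, n_starts: int, seed: int | None) -> float:
    if k == 1:
        return float(((X - X.mean(axis=0)) ** 2).sum())
    model, _ = kmeans_fit(X, k, n_starts=n_starts, seed=seed, compute_silhouette=False)
    return model.wcss


# --------------------------------------------------------------------------- #
# Gap statistic
# --------------------------------------------------------------------------- #


@dataclass
class GapResult:
    k_range: list[int]
    gap: list[float]
    se: list[float]
    k_gap: int
    log_wcss_obs: list[float]


def gap_statistic(
    X, k_range=DEFAULT_K_RANGE_GAP, B: int = 50, seed: int = 0, *, n_starts: int = 5
) -> GapResult:
    """Gap statistic with a PCA-aligned uniform reference and the 1-SE rule.

    ``Gap(k) = E*[log W_ref(k)] - log W_obs(k)`` over ``B`` reference datasets
    drawn uniformly in the bounding box of the principal-axes rotation of X;
    the reported SE carries the ``sqrt(1 + 1/B)`` factor, and the selected k
    is the smallest with ``Gap(k) >= Gap(k+1) - SE(k+1)``.
    """
    if B < 10:
        raise ValueError("B must be at least 10")
    M = _as_array(X)
    if M.std(axis=0).min() <= 0:
        raise ValueError("degenerate input: a column has zero variance")
    ks = list(k_range)
    rng = np.random.default_rng(seed)
    centered = M - M.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    rotated = centered @ Vt.T
    lo, hi = rotated.min(axis=0), rotated.max(axis=0)

    log_w_obs = [np.log(_kmeans_wcss(M, k, n_starts, int(rng.integers(2**31 - 1)))) for k in ks]
    log_w_ref = np.empty((B, len(ks)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=rotated.shape) @ Vt
        for j, k in enumerate(ks):
            log_w_ref[b, j] = np.log(_kmeans_wcss(ref, k, n_starts, int(rng.integers(2**31 - 1))))
    gap = log_w_ref.mean(axis=0) - np.asarray(log_w_obs)
    sd = log_w_ref.std(axis=0, ddof=0)
    se = sd * np.sqrt(1.0 + 1.0 / B)

    k_gap = ks[-1]
    for j in range(len(ks) - 1):
        if gap[j] >= gap[j + 1] - se[j + 1]:
            k_gap = ks[j]
            break
    return GapResult(ks, [float(g) for g in gap], [float(s) for s in se], int(k_gap), log_w_obs)


# --------------------------------------------------------------------------- #
# Silhouette maximisation
# --------------------------------------------------------------------------- #


def silhouette_selection(
    X, k_range=DEFAULT_K_RANGE, *, n_starts: int = 10, seed: int = 0
) -> tuple[int, dict[int, float]]:
    """k maximising the mean silhouette of the k-means partition (ties -> smaller k)."""
    M = _as_array(X)
    ks = [k for k in k_range if 2 <= k <= len(M) - 1]
    if not ks:
        raise ValueError("k_range must intersect [2, n-1]")
    scores = {}
    for k in ks:
        _, part = kmeans_fit(M, k, n_starts=n_starts, seed=seed, compute_silhouette=False)
        scores[k] = float(silhouette_score(M, part.labels))
    best = max(scores.values())
    k_sil = min(k for k, s in scores.items() if s >= best - 1e-12)
    return k_sil, scores


# --------------------------------------------------------------------------- #
# Cluster-validity index ensemble (majority vote)
# --------------------------------------------------------------------------- #


def _dunn_index(D: np.ndarray, labels: np.ndarray) -> float:
    ids = np.unique(labels)
    diam = 0.0
    for c in ids:
        mask = labels == c
        if mask.sum() > 1:
            diam = max(diam, float(D[np.ix_(mask, mask)].max()))
    sep = np.inf
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            sep = min(sep, float(D[np.ix_(labels == a, labels == b)].min()))
    if diam == 0:
        return np.inf
    return sep / diam


def _c_index(D: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    d = D[iu]
    same = (labels[iu[0]] == labels[iu[1]])
    nw = int(same.sum())
    if nw == 0:
        return 0.0
    s = float(d[same].sum())
    d_sorted = np.sort(d)
    s_min = float(d_sorted[:nw].sum())
    s_max = float(d_sorted[-nw:].sum())
    if s_max == s_min:
        return 0.0
    return (s - s_min) / (s_max - s_min)


@dataclass
class EnsembleVote:
    votes: dict[str, int]  # index name -> voted k
    tally: dict[int, int]  # k -> number of votes
    k_majority: int
    runner_up: int | None


def index_ensemble_vote(
    X, k_range=DEFAULT_K_RANGE, *, n_starts: int = 10, seed: int = 0
) -> EnsembleVote:
    """Majority vote of seven cluster-validity indices on k-means partitions.

    Optimum rules: Calinski-Harabasz, silhouette, Dunn and Krzanowski-Lai are
    maximised; Davies-Bouldin and C-index minimised; Hartigan picks the
    smallest k whose index drops to 10 or below (largest drop if none does).
    Ties inside an index go to the smaller k; ties in the vote tally go to the
    smaller k.  The runner-up (second-most-voted k) is reported as the
    fallback used when the winner later fails the acceptance gates.
    """
    M = _as_array(X)
    n, p = M.shape
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if len(ks) < 1:
        raise ValueError("no feasible k in range")
    D = squareform(pdist(M))
    parts: dict[int, np.ndarray] = {}
    wcss: dict[int, float] = {}
    rng = np.random.default_rng(seed)
    for k in range(min(ks) - 1, max(ks) + 2):
        if k < 1 or k > n:
            continue
        if k == 1:
            wcss[k] = float(((M - M.mean(axis=0)) ** 2).sum())
            continue
        model, part = kmeans_fit(
            M, k, n_starts=n_starts, seed=int(rng.integers(2**31 - 1)), compute_silhouette=False
        )
        parts[k] = part.labels
        wcss[k] = model.wcss

    def argbest(scores: dict[int, float], maximise: bool) -> int:
        vals = {k: (v if maximise else -v) for k, v in scores.items() if np.isfinite(v)}
        if not vals:
            raise ValueError("index undefined for all k")
        best = max(vals.values())
        return min(k for k, v in vals.items() if v >= best - 1e-12)

    votes: dict[str, int] = {}
    votes["calinski_harabasz"] = argbest(
        {k: calinski_harabasz_score(M, parts[k]) for k in ks}, True
    )
    votes["davies_bouldin"] = argbest({k: davies_bouldin_score(M, parts[k]) for k in ks}, False)
    votes["silhouette"] = argbest({k: silhouette_score(M, parts[k]) for k in ks}, True)
    votes["dunn"] = argbest({k: _dunn_index(D, parts[k]) for k in ks}, True)
    votes["c_index"] = argbest({k: -_c_index(D, parts[k]) for k in ks}, True)

    hartigan = {
        k: (wcss[k] / wcss[k + 1] - 1.0) * (n - k - 1)
        for k in range(max(1, min(ks) - 1), max(ks) + 1)
        if k in wcss and k + 1 in wcss
    }
    below = [k for k in ks if k in hartigan and hartigan[k] <= 10.0]
    if below:
        votes["hartigan"] = min(below)
    else:
        # no k reaches the <=10 rule: vote the k sitting after the largest
        # collapse of H, i.e. argmax of H(k-1) - H(k)
        drops = {k: hartigan[k - 1] - hartigan[k] for k in ks if k - 1 in hartigan and k in hartigan}
        votes["hartigan"] = argbest(drops, True) if drops else ks[0]

    def diff(k: int) -> float:
        return (k - 1) ** (2.0 / p) * wcss[k - 1] - k ** (2.0 / p) * wcss[k]

    kl = {}
    for k in ks:
        if k - 1 in wcss and k + 1 in wcss and k >= 2:
            denom = diff(k + 1)
            kl[k] = abs(diff(k) / denom) if denom != 0 else np.inf
    votes["krzanowski_lai"] = argbest(kl, True) if kl else ks[0]

    tally: dict[int, int] = {}
    for k in votes.values():
        tally[k] = tally.get(k, 0) + 1
    ordered = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    k_majority = ordered[0][0]
    runner_up = ordered[1][0] if len(ordered) > 1 else None
    return EnsembleVote(votes, tally, k_majority, runner_up)


# --------------------------------------------------------------------------- #
# k-selection report
# --------------------------------------------------------------------------- #


@dataclass
class KSelectionReport:
    k_range: list[int]
    wcss: dict[int, float]  # elbow curve
    mean_silhouette: dict[int, float]
    gap: GapResult
    ensemble: EnsembleVote
    k_by_method: dict[str, int]
    final_k_order: list[int]  # candidate order: majority vote, then runner-up
    provenance: str

    def to_dict(self) -> dict:
        return {
            "k_range": self.k_range,
            "wcss": {str(k): v for k, v in self.wcss.items()},
            "mean_silhouette": {str(k): v for k, v in self.mean_silhouette.items()},
            "gap": {
                "k_range": self.gap.k_range,
                "gap": self.gap.gap,
                "se": self.gap.se,
                "k_gap": self.gap.k_gap,
            },
            "ensemble_votes": self.ensemble.votes,
            "ensemble_tally": {str(k): v for k, v in self.ensemble.tally.items()},
            "k_by_method": self.k_by_method,
            "final_k_order": self.final_k_order,
            "provenance": self.provenance,
        }


def k_selection_report(
    X,
    k_range_gap=DEFAULT_K_RANGE_GAP,
    k_range=DEFAULT_K_RANGE,
    *,
    gap_B: int = 50,
    n_starts: int = 10,
    seed: int = 0,
) -> KSelectionReport:
    """Run all four k-selection methods and collate the candidate k order."""
    M = _as_array(X)
    gap = gap_statistic(M, k_range_gap, B=gap_B, seed=seed, n_starts=n_starts)
    k_sil, sil_scores = silhouette_selection(M, k_range, n_starts=n_starts, seed=seed)
    ensemble = index_ensemble_vote(M, k_range, n_starts=n_starts, seed=seed)
    wcss = {}
    rng = np.random.default_rng(seed)
    for k in k_range_gap:
        wcss[k] = _kmeans_wcss(M, k, n_starts, int(rng.integers(2**31 - 1)))
    order = [ensemble.k_majority]
    if ensemble.runner_up is not None and ensemble.runner_up not in order:
        order.append(ensemble.runner_up)
    return KSelectionReport(
        k_range=list(k_range),
        wcss=wcss,
        mean_silhouette=sil_scores,
        gap=gap,
        ensemble=ensemble,
        k_by_method={
            "gap": gap.k_gap,
            "silhouette": k_sil,
            "ensemble_majority": ensemble.k_majority,
        },
        final_k_order=order,
        provenance=(
            f"gap={gap.k_gap}, silhouette={k_sil}, ensemble majority={ensemble.k_majority} "
            f"(runner-up {ensemble.runner_up}); candidates tried in majority-then-runner-up order"
        ),
    )


# --------------------------------------------------------------------------- #
# Gated model selection
# --------------------------------------------------------------------------- #


@dataclass
class GateConfig:
    jaccard_threshold: float = JACCARD_THRESHOLD
    min_cluster_silhouette: float = 0.0
    variable_alpha: float = ALPHA
    bootstrap_B: int = 100


@dataclass
class GateAudit:
    candidate: str
    k: int
    jaccard: dict[int, float] | None = None
    cluster_silhouette: tuple[float, ...] | None = None
    variable_p: dict[str, float] | None = None
    passed: bool = False
    failed_gate: str | None = None


@dataclass
class SelectionResult:
    model: ClusterModel | None
    partition: Partition | None
    accepted: bool
    audit: list[GateAudit]
    k_report: KSelectionReport

    @property
    def no_acceptable_clustering(self) -> bool:
        return not self.accepted


def evaluate_gates(
    train: pd.DataFrame,
    Z,
    model: ClusterModel,
    part: Partition,
    gates: GateConfig,
    seed: int,
) -> GateAudit:
    """Evaluate the three acceptance gates for one fitted candidate.

    Gates are checked in increasing cost order: per-cluster mean silhouette
    (>= 0), all input variables significantly different across clusters
    (omnibus p < alpha), clusterwise bootstrap Jaccard (> threshold).
    """
    audit = GateAudit(
        candidate=f"{model.algorithm}/{model.distance}/{model.linkage}", k=model.k
    )
    audit.cluster_silhouette = part.cluster_mean_silhouette
    if part.cluster_mean_silhouette is None or any(
        s < gates.min_cluster_silhouette for s in part.cluster_mean_silhouette
    ):
        audit.failed_gate = "cluster mean silhouette below 0"
        return audit
    variables = model.scaling.variables if model.scaling else train.columns
    pvals = {}
    for v in variables:
        try:
            comp = compare_variable(train[v], part.labels, v, seed=seed)
        except ValueError as err:  # e.g. singleton clusters from a loose linkage
            audit.failed_gate = f"variable comparison undefined for {v!r}: {err}"
            return audit
        pvals[v] = comp.p
    audit.variable_p = pvals
    not_diff = [v for v, p in pvals.items() if p >= gates.variable_alpha]
    if not_diff:
        audit.failed_gate = f"variables not significantly different: {not_diff}"
        return audit
    stab = bootstrap_stability(
        Z, model, part.labels, B=gates.bootstrap_B, seed=seed, threshold=gates.jaccard_threshold
    )
    audit.jaccard = stab.cluster_jaccard
    if not stab.all_pass:
        low = [c for c, ok in stab.passed.items() if not ok]
        audit.failed_gate = f"bootstrap Jaccard <= {gates.jaccard_threshold} for clusters {low}"
        return audit
    audit.passed = True
    return audit


def select_model(
    train: pd.DataFrame,
    variable_set: str = "full5",
    *,
    roster=DEFAULT_ROSTER,
    gates: GateConfig | None = None,
    k_report: KSelectionReport | None = None,
    gap_B: int = 50,
    n_starts: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Full gated selection of a clustering configuration on a training table.

    Computes the k-selection report, then walks the candidate grid —
    algorithms in the roster's preference order, k in majority-then-runner-up
    order — and returns the first candidate that passes every acceptance
    gate, with a full audit trail.  When nothing passes, an explicit
    unaccepted result is returned.
    """
    if not roster:
        raise ValueError("empty algorithm roster")
    gates = gates or GateConfig()
    vs = get_variable_set(variable_set)
    scaler = standardize_fit(train, vs)
    Z = standardize_apply(train, scaler)
    if k_report is None:
        k_report = k_selection_report(Z, gap_B=gap_B, n_starts=n_starts, seed=seed)
    audits: list[GateAudit] = []
    for algorithm, distance, linkage in roster:
        for k in k_report.final_k_order:
            try:
                if algorithm == "kmeans":
                    model, part = kmeans_fit(
                        Z, k, n_starts=max(n_starts, 10), seed=seed,
                        scaling=scaler, variable_set=vs.id,
                    )
                elif algorithm == "kmedoids":
                    model, part = kmedoids_fit(
                        Z, k, distance=distance, seed=seed,
                        scaling=scaler, variable_set=vs.id,
                    )
                else:
                    model, part, _ = hierarchical_fit(
                        Z, k, distance=distance, linkage=linkage,
                        scaling=scaler, variable_set=vs.id,
                    )
            except Exception as err:
                logger.warning("candidate %s/%s k=%d failed to fit: %s", algorithm, distance, k, err)
                audits.append(
                    GateAudit(f"{algorithm}/{distance}/{linkage}", k, failed_gate=f"fit error: {err}")
                )
                continue
            audit = evaluate_gates(train, Z, model, part, gates, seed)
            audits.append(audit)
            if audit.passed:
                return SelectionResult(model, part, True, audits, k_report)
    logger.info("no candidate passed all acceptance gates")
    return SelectionResult(None, None, False, audits, k_report)
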