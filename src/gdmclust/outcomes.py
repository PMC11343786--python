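"""Cluster-wise comparison of input variables and clinical outcomes.

The testing scheme mirrors routine clinical-epidemiology practice for
three-group comparisons.  Continuous variables are routed by a Shapiro-Wilk
normality check (on pooled residuals about the group medians): normal
variables get one-way ANOVA followed by Fisher's protected LSD post hoc
t-tests, non-normal ones get Kruskal-Wallis followed by Dunn's rank tests.
Binary outcomes get a Pearson chi-square omnibus (exact conditional test when
expected counts are small) and a cluster-factor logistic regression whose
likelihood-ratio test backs the pairwise odds ratios.  Post hoc stages are
*protected*: pairwise results are only produced when the omnibus test is
significant at 0.05.  p values are unadjusted by default (explorative stance);
Bonferroni / Benjamini-Hochberg adjustment of the pairwise stage is available
behind a flag.

Available-case accounting follows the published table convention: each
outcome's N_tot and per-cluster denominators count the rows where that
outcome was recorded.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

ALPHA = 0.05  # two-sided significance level used throughout


@dataclass
class OddsRatio:
    pair: tuple[int, int]
    value: float  # odds(cluster i) / odds(cluster j)
    ci_low: float
    ci_high: float
    unbounded: bool = False  # separation: a cell count of 0 makes the OR unbounded


@dataclass
class OutcomeComparison:
    """Omnibus + (protected) pairwise comparison of one variable across clusters."""

    name: str
    kind: str  # continuous | binary
    route: str  # anova+lsd | kruskal+dunn | chi2 | fisher | logistic-lrt
    statistic: float
    df: float
    p: float
    n_per_cluster: tuple[int, ...]
    pairwise: dict[tuple[int, int], float] = field(default_factory=dict)
    odds_ratios: dict[tuple[int, int], OddsRatio] = field(default_factory=dict)
    counts: tuple[int, ...] | None = None  # binary: events per cluster
    notes: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


# --------------------------------------------------------------------------- #
# helpers
# --------------------------------------------------------------------------- #


def _groups(values, labels) -> tuple[list[np.ndarray], list[int]]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    cluster_ids = sorted(int(c) for c in np.unique(labels))
    return [values[labels == c] for c in cluster_ids], cluster_ids


def _adjust(pvals: dict, method: str | None) -> dict:
    if method is None or not pvals:
        return pvals
    from statsmodels.stats.multitest import multipletests

    keys = list(pvals)
    method_map = {"bonferroni": "bonferroni", "bh": "fdr_bh"}
    _, adj, _, _ = multipletests([pvals[k] for k in keys], method=method_map[method])
    return dict(zip(keys, (float(p) for p in adj)))


# --------------------------------------------------------------------------- #
# Normality routing
# --------------------------------------------------------------------------- #


def normality_route(values, *, alpha: float = ALPHA, seed: int = 0) -> str:
    """Classify a sample as ``"normal"`` or ``"non-normal"`` by Shapiro-Wilk.

    Samples larger than 5000 are subsampled (Shapiro-Wilk's supported range);
    constant vectors are non-normal with a warning; n < 3 is an error.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ValueError("normality check needs at least 3 non-missing values")
    if np.ptp(x) == 0:
        warnings.warn("constant vector routed as non-normal", stacklevel=2)
        return "non-normal"
    if len(x) > 5000:
        rng = np.random.default_rng(seed)
        x = rng.choice(x, 5000, replace=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.shapiro(x).pvalue
    return "normal" if p >= alpha else "non-normal"


def route_for_groups(values, labels, *, seed: int = 0) -> str:
    """Route a group comparison from pooled residuals about the group medians."""
    groups, _ = _groups(values, labels)
    resid = np.concatenate([g - np.median(g) for g in groups if len(g)])
    return normality_route(resid, seed=seed)


# --------------------------------------------------------------------------- #
# Continuous outcomes
# --------------------------------------------------------------------------- #


def anova_fisher_lsd(
    values, labels, name: str = "", *, adjust: str | None = None
) -> OutcomeComparison:
    """One-way ANOVA with Fisher's protected LSD post hoc stage.

    Pairwise t-tests use the pooled within-group mean square (the classical
    LSD) and run only when the omnibus F-test is significant at 0.05.
    """
    groups, ids = _groups(values, labels)
    notes = []
    usable = [(g, c) for g, c in zip(groups, ids) if len(g) >= 2]
    if len(usable) < len(groups):
        dropped = [c for g, c in zip(groups, ids) if len(g) < 2]
        notes.append(f"clusters excluded (<2 observations): {dropped}")
        logger.warning("anova: excluding clusters %s with <2 observations", dropped)
    groups = [g for g, _ in usable]
    ids = [c for _, c in usable]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    n = sum(len(g) for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n - k
    mse = ss_within / df2
    F = (ss_between / df1) / mse if mse > 0 else 0.0
    p = float(stats.f.sf(F, df1, df2)) if mse > 0 else 1.0
    comp = OutcomeComparison(
        name=name,
        kind="continuous",
        route="anova+lsd",
        statistic=float(F),
        df=df1,
        p=p,
        n_per_cluster=tuple(len(g) for g in groups),
        notes=notes,
    )
    if p < ALPHA:
        pw = {}
        for (i, gi), (j, gj) in itertools.combinations(zip(ids, groups), 2):
            se = math.sqrt(mse * (1 / len(gi) + 1 / len(gj)))
            t = (gi.mean() - gj.mean()) / se
            pw[(i, j)] = float(2 * stats.t.sf(abs(t), df2))
        comp.pairwise = _adjust(pw, adjust)
    return comp


def kruskal_dunn(
    values, labels, name: str = "", *, adjust: str | None = None
) -> OutcomeComparison:
    """Kruskal-Wallis omnibus (tie-corrected) with protected Dunn post hoc tests.

    Dunn's z statistics compare mean ranks with the tie-corrected variance
    ``(N(N+1)/12 - T)(1/n_i + 1/n_j)`` where ``T = sum(t^3 - t)/(12(N-1))``;
    p values are two-sided and unadjusted unless ``adjust`` is given.
    """
    groups, ids = _groups(values, labels)
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        comp = OutcomeComparison(
            name=name,
            kind="continuous",
            route="kruskal+dunn",
            statistic=0.0,
            df=len(groups) - 1,
            p=1.0,
            n_per_cluster=tuple(len(g) for g in groups),
            notes=["all values tied"],
        )
        return comp
    H, p = stats.kruskal(*groups)
    comp = OutcomeComparison(
        name=name,
        kind="continuous",
        route="kruskal+dunn",
        statistic=float(H),
        df=len(groups) - 1,
        p=float(p),
        n_per_cluster=tuple(len(g) for g in groups),
    )
    if p < ALPHA:
        N = len(pooled)
        ranks = stats.rankdata(pooled)
        rank_groups = np.split(ranks, np.cumsum([len(g) for g in groups])[:-1])
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
        var0 = N * (N + 1) / 12.0 - tie_term
        pw = {}
        for (i, ri), (j, rj) in itertools.combinations(zip(ids, rank_groups), 2):
            se = math.sqrt(var0 * (1 / len(ri) + 1 / len(rj)))
            z = (ri.mean() - rj.mean()) / se
            pw[(i, j)] = float(2 * stats.norm.sf(abs(z)))
        comp.pairwise = _adjust(pw, adjust)
    return comp


# --------------------------------------------------------------------------- #
# Binary outcomes
# --------------------------------------------------------------------------- #


def _binary_table(values, labels) -> tuple[np.ndarray, list[int]]:
    """2 x k table (rows: event yes/no) from available cases."""
    groups, ids = _groups(values, labels)
    bad = [c for g, c in zip(groups, ids) if len(g) and not np.isin(g, (0.0, 1.0)).all()]
    if bad:
        raise ValueError(f"non-binary values in outcome for clusters {bad}")
    yes = np.array([g.sum() for g in groups])
    no = np.array([len(g) - g.sum() for g in groups])
    return np.vstack([yes, no]).astype(int), ids


def exact_conditional_p(table: np.ndarray) -> float:
    """Exact conditional (Fisher-type) test for a 2 x k table.

    Enumerates all tables with the observed margins; the p value sums the
    multivariate hypergeometric probabilities of tables no more probable than
    the observed one.  For 2 x 2 this reduces to Fisher's exact test.
    """
    table = np.asarray(table, dtype=int)
    m = int(table[0].sum())  # total events
    col = table.sum(axis=0)
    N = int(col.sum())

    def log_prob(xs):
        lp = -(gammaln(N + 1) - gammaln(m + 1) - gammaln(N - m + 1))
        for x, n_i in zip(xs, col):
            lp += gammaln(n_i + 1) - gammaln(x + 1) - gammaln(n_i - x + 1)
        return lp

    lp_obs = log_prob(table[0])
    total = 0.0

    def rec(idx, remaining, xs):
        nonlocal total
        if idx == len(col) - 1:
            if remaining <= col[idx]:
                lp = log_prob(xs + [remaining])
                if lp <= lp_obs + 1e-9:
                    total += math.exp(lp)
            return
        for x in range(min(remaining, col[idx]) + 1):
            rec(idx + 1, remaining - x, xs + [x])

    rec(0, m, [])
    return min(1.0, total)


def contingency_test(
    values, labels, name: str = "", *, adjust: str | None = None
) -> OutcomeComparison:
    """Pearson chi-square across clusters, exact conditional test when sparse.

    The chi-square (no continuity correction) is used when every expected
    count is at least 5, otherwise the exact conditional test.  Pairwise 2 x 2
    tests (same switching rule) run only when the omnibus is significant.
    """
    table, ids = _binary_table(values, labels)
    if (table.sum(axis=0) == 0).any() or table.sum() == 0:
        raise ValueError("empty margin in contingency table")
    notes = []
    if table.sum(axis=1).min() == 0:
        # outcome all-0 or all-1 everywhere: no association testable
        comp = OutcomeComparison(
            name=name,
            kind="binary",
            route="chi2",
            statistic=0.0,
            df=len(ids) - 1,
            p=1.0,
            n_per_cluster=tuple(int(x) for x in table.sum(axis=0)),
            counts=tuple(int(x) for x in table[0]),
            notes=["degenerate outcome margin"],
        )
        return comp
    chi2, p_chi, dof, expected = stats.chi2_contingency(table, correction=False)
    if expected.min() >= 5:
        route, statistic, p = "chi2", float(chi2), float(p_chi)
    else:
        route, statistic, p = "fisher", float(chi2), exact_conditional_p(table)
        notes.append("expected count < 5: exact conditional test")
    comp = OutcomeComparison(
        name=name,
        kind="binary",
        route=route,
        statistic=statistic,
        df=dof,
        p=p,
        n_per_cluster=tuple(int(x) for x in table.sum(axis=0)),
        counts=tuple(int(x) for x in table[0]),
        notes=notes,
    )
    if p < ALPHA and len(ids) > 2:
        pw = {}
        for a, b in itertools.combinations(range(len(ids)), 2):
            sub = table[:, [a, b]]
            if (sub.sum(axis=0) == 0).any() or sub.sum(axis=1).min() == 0:
                continue
            chi2_ab, p_ab, _, exp_ab = stats.chi2_contingency(sub, correction=False)
            if exp_ab.min() < 5:
                p_ab = exact_conditional_p(sub)
            pw[(ids[a], ids[b])] = float(p_ab)
        comp.pairwise = _adjust(pw, adjust)
    return comp


def logistic_lrt(
    values, labels, name: str = "", *, adjust: str | None = None
) -> OutcomeComparison:
    """Cluster-factor logistic regression with likelihood-ratio omnibus test.

    Fits ``logit P(event) = intercept + cluster indicators`` by maximum
    likelihood, tests it against the intercept-only model, and (when the LRT
    is significant) reports pairwise odds ratios ``odds_i / odds_j`` with Wald
    95% CIs.  A cluster with no events (or no non-events) makes the affected
    ORs unbounded: these are flagged and the LRT is computed from the
    closed-form saturated likelihood.
    """
    import statsmodels.api as sm

    table, ids = _binary_table(values, labels)
    k = len(ids)
    yes, tot = table[0], table.sum(axis=0)
    if (tot == 0).any():
        raise ValueError("empty cluster in logistic comparison")
    if table.sum(axis=1).min() == 0:
        raise ValueError("outcome has a single level; logistic model undefined")
    separated = bool((yes == 0).any() or (yes == tot).any())
    notes = []

    # omnibus LRT: the cluster-factor model is saturated in cluster, so the
    # maximised log-likelihoods have closed form and remain valid under separation
    def bin_ll(y, n):
        if y == 0 or y == n:
            return 0.0
        p_hat = y / n
        return y * math.log(p_hat) + (n - y) * math.log(1 - p_hat)

    ll_full = sum(bin_ll(int(y), int(n)) for y, n in zip(yes, tot))
    ll_null = bin_ll(int(yes.sum()), int(tot.sum()))
    lrt = 2.0 * (ll_full - ll_null)
    p = float(stats.chi2.sf(lrt, k - 1))

    comp = OutcomeComparison(
        name=name,
        kind="binary",
        route="logistic-lrt",
        statistic=float(lrt),
        df=k - 1,
        p=p,
        n_per_cluster=tuple(int(x) for x in tot),
        counts=tuple(int(x) for x in yes),
        notes=notes,
    )
    if p >= ALPHA:
        return comp

    if not separated:
        # grouped-data GLM: indicator design, cluster ids[0] as reference
        endog = np.vstack([yes, tot - yes]).T.astype(float)
        exog = np.ones((k, k))
        for j in range(1, k):
            exog[:, j] = (np.arange(k) == j).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # near-boundary fits warn spuriously
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        beta = np.concatenate([[0.0], fit.params[1:]]) + fit.params[0]  # per-cluster logit
        cov = fit.cov_params()
        pw, ors = {}, {}
        zcrit = stats.norm.ppf(0.975)
        for a, b in itertools.combinations(range(k), 2):
            # contrast of cluster logits a - b in the indicator parametrisation
            ca = np.zeros(k)
            if a > 0:
                ca[a] = 1.0
            if b > 0:
                ca[b] -= 1.0
            est = float(ca @ fit.params)
            se = float(np.sqrt(ca @ cov @ ca))
            zval = est / se
            pw[(ids[a], ids[b])] = float(2 * stats.norm.sf(abs(zval)))
            ors[(ids[a], ids[b])] = OddsRatio(
                (ids[a], ids[b]),
                math.exp(est),
                math.exp(est - zcrit * se),
                math.exp(est + zcrit * se),
            )
        comp.pairwise = _adjust(pw, adjust)
        comp.odds_ratios = ors
        _ = beta  # per-cluster logits retained for debugging only
    else:
        notes.append("separation: odds ratios unbounded for affected pairs")
        pw, ors = {}, {}
        for a, b in itertools.combinations(range(k), 2):
            cells = (yes[a], tot[a] - yes[a], yes[b], tot[b] - yes[b])
            if 0 in cells:
                value = math.inf if (cells[1] == 0 or cells[2] == 0) else 0.0
                ors[(ids[a], ids[b])] = OddsRatio(
                    (ids[a], ids[b]), value, math.nan, math.nan, unbounded=True
                )
                sub = np.array([[yes[a], yes[b]], [tot[a] - yes[a], tot[b] - yes[b]]])
                pw[(ids[a], ids[b])] = exact_conditional_p(sub)
            else:
                lor = math.log(cells[0] * cells[3] / (cells[1] * cells[2]))
                se = math.sqrt(sum(1.0 / c for c in cells))
                zcrit = stats.norm.ppf(0.975)
                ors[(ids[a], ids[b])] = OddsRatio(
                    (ids[a], ids[b]),
                    math.exp(lor),
                    math.exp(lor - zcrit * se),
                    math.exp(lor + zcrit * se),
                )
                pw[(ids[a], ids[b])] = float(2 * stats.norm.sf(abs(lor / se)))
        comp.pairwise = _adjust(pw, adjust)
        comp.odds_ratios = ors
    return comp


# --------------------------------------------------------------------------- #
# Dispatch + profiles
# --------------------------------------------------------------------------- #


def is_binary(values) -> bool:
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    return len(x) > 0 and np.isin(x, (0.0, 1.0)).all()


def compare_variable(
    values, labels, name: str = "", *, seed: int = 0, adjust: str | None = None
) -> OutcomeComparison:
    """Route one variable to the appropriate omnibus + post hoc scheme."""
    if is_binary(values):
        comp = contingency_test(values, labels, name, adjust=adjust)
        return comp
    route = route_for_groups(values, labels, seed=seed)
    if route == "normal":
        return anova_fisher_lsd(values, labels, name, adjust=adjust)
    return kruskal_dunn(values, labels, name, adjust=adjust)


def compare_outcomes(
    table: pd.DataFrame,
    labels,
    outcome_columns: list[str],
    *,
    seed: int = 0,
    adjust: str | None = None,
    logistic: bool = True,
) -> dict[str, OutcomeComparison]:
    """Compare each outcome column across clusters; binary outcomes also get
    the logistic-LRT odds-ratio analysis attached."""
    results: dict[str, OutcomeComparison] = {}
    for name in outcome_columns:
        values = table[name]
        comp = compare_variable(values, labels, name, seed=seed, adjust=adjust)
        if comp.kind == "binary" and logistic:
            try:
                logit = logistic_lrt(values, labels, name, adjust=adjust)
                comp.odds_ratios = logit.odds_ratios
                comp.notes.extend(n for n in logit.notes if n not in comp.notes)
            except ValueError as err:
                comp.notes.append(f"logistic analysis unavailable: {err}")
        results[name] = comp
    return results


@dataclass
class ClusterProfile:
    """Per-cluster summary table in the published layout.

    ``formatted`` holds display strings — "median (Q1-Q3)" for continuous
    rows, "n (pct)" with the percentage printed to 2 decimals for binary rows;
    ``n_tot`` and ``denominators`` carry the available-case accounting.
    """

    variables: list[str]
    cluster_ids: list[int]
    formatted: pd.DataFrame
    n_tot: dict[str, int]
    denominators: dict[str, tuple[int, ...]]
    percentages: dict[str, tuple[float, ...]]  # binary rows only
    medians: dict[str, tuple[float, ...]]  # continuous rows only


def cluster_profile(table: pd.DataFrame, labels, variables: list[str]) -> ClusterProfile:
    """Summarise variables per cluster with available-case denominators.

    Binary variables (values in {0,1,NaN}) report ``n (pct)`` where
    ``pct = round(count / cluster_denominator * 100, 2)``; continuous ones
    report ``median (Q1-Q3)``.  A fully missing variable is still emitted,
    with N_tot = 0.
    """
    labels = np.asarray(labels)
    cluster_ids = sorted(int(c) for c in np.unique(labels))
    rows = {}
    n_tot: dict[str, int] = {}
    denoms: dict[str, tuple[int, ...]] = {}
    pcts: dict[str, tuple[float, ...]] = {}
    meds: dict[str, tuple[float, ...]] = {}

    def fmt(x: float) -> str:
        return f"{x:.2f}".rstrip("0").rstrip(".") if x == x else "NA"

    for name in variables:
        values = np.asarray(table[name], dtype=float)
        avail = ~np.isnan(values)
        n_tot[name] = int(avail.sum())
        d = tuple(int((avail & (labels == c)).sum()) for c in cluster_ids)
        denoms[name] = d
        cells = []
        if is_binary(values) and n_tot[name] > 0:
            counts = tuple(
                int(values[avail & (labels == c)].sum()) for c in cluster_ids
            )
            pct = tuple(
                round(cnt / den * 100, 2) if den else math.nan
                for cnt, den in zip(counts, d)
            )
            pcts[name] = pct
            cells = [
                f"{cnt} ({p:.2f})" if den else "0 (NA)"
                for cnt, p, den in zip(counts, pct, d)
            ]
        elif n_tot[name] == 0:
            cells = ["NA"] * len(cluster_ids)
        else:
            med = []
            for c, den in zip(cluster_ids, d):
                x = values[avail & (labels == c)]
                if len(x) == 0:
                    med.append(math.nan)
                    cells.append("NA")
                    continue
                q1, q2, q3 = np.percentile(x, [25, 50, 75])
                med.append(float(q2))
                cells.append(f"{fmt(q2)} ({fmt(q1)}–{fmt(q3)})")
            meds[name] = tuple(med)
        rows[name] = {"N_tot": n_tot[name], **dict(zip(cluster_ids, cells))}

    formatted = pd.DataFrame.from_dict(rows, orient="index")
    formatted.columns = ["N_tot"] + [f"cluster_{c}" for c in cluster_ids]
    return ClusterProfile(
        variables=list(variables),
        cluster_ids=cluster_ids,
        formatted=formatted,
        n_tot=n_tot,
        denominators=denoms,
        percentages=pcts,
        medians=meds,
    )
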