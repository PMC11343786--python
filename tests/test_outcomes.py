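"""Statistical testing scheme: normality routing, protected post hoc stages,
exact tests against enumeration oracles, odds ratios, profile tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gdmclust.outcomes import (
    anova_fisher_lsd,
    cluster_profile,
    compare_variable,
    contingency_test,
    exact_conditional_p,
    kruskal_dunn,
    logistic_lrt,
    normality_route,
)

# Training-set drug-prescription row: (events, available) per cluster
DRUG_COUNTS = ((84, 212), (47, 364), (44, 440))


def binary_fixture(counts, sizes=None):
    """Rows + labels reconstructing a published n/N row, missing cells NaN."""
    values, labels = [], []
    for cluster, (yes, avail) in enumerate(counts, start=1):
        size = avail if sizes is None else sizes[cluster - 1]
        col = [1.0] * yes + [0.0] * (avail - yes) + [np.nan] * (size - avail)
        values.extend(col)
        labels.extend([cluster] * size)
    return np.array(values), np.array(labels)


class TestNormalityRoute:
    def test_normal_samples_routed_normal(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=500)
            hits += normality_route(x) == "normal"
        assert hits >= 90  # nominal 5% level

    def test_exponential_samples_routed_non_normal(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(size=500)
            hits += normality_route(x) == "non-normal"
        assert hits >= 99

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_route([1.0, 2.0])

    def test_constant_vector_warns_non_normal(self):
        with pytest.warns(UserWarning):
            assert normality_route([3.0] * 10) == "non-normal"

    def test_large_sample_subsampled(self):
        x = np.random.default_rng(0).normal(size=20_000)
        assert normality_route(x) in ("normal", "non-normal")


class TestAnovaLsd:
    def test_identical_groups_no_pairwise_stage(self):
        x = np.random.default_rng(0).normal(size=30)
        values = np.concatenate([x, x, x])
        labels = np.repeat([1, 2, 3], 30)
        comp = anova_fisher_lsd(values, labels)
        assert comp.statistic == pytest.approx(0.0, abs=1e-12)
        assert comp.pairwise == {}

    def test_shifted_group_detected_with_protection(self):
        rng = np.random.default_rng(1)
        values = np.concatenate(
            [rng.normal(0, 1, 50), rng.normal(0, 1, 50), rng.normal(2, 1, 50)]
        )
        labels = np.repeat([1, 2, 3], 50)
        comp = anova_fisher_lsd(values, labels)
        assert comp.p < 0.001
        assert comp.pairwise[(1, 3)] < 0.05 and comp.pairwise[(2, 3)] < 0.05

    def test_two_groups_reduce_to_pooled_t_test(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 25), rng.normal(0.7, 1, 30)
        comp = anova_fisher_lsd(np.concatenate([a, b]), np.repeat([1, 2], [25, 30]))
        t_p = stats.ttest_ind(a, b).pvalue  # F = t^2 identity
        assert comp.p == pytest.approx(t_p, rel=1e-10)

    def test_undersized_group_excluded_with_note(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 9.0])
        labels = np.array([1, 1, 2, 2, 3])
        comp = anova_fisher_lsd(values, labels)
        assert comp.n_per_cluster == (2, 2)
        assert any("excluded" in n for n in comp.notes)


class TestKruskalDunn:
    def test_rank_formula_hand_value(self):
        """{1..9} split into consecutive thirds: H = 7.2 by the rank formula."""
        comp = kruskal_dunn(np.arange(1.0, 10.0), np.repeat([1, 2, 3], 3))
        assert comp.statistic == pytest.approx(7.2, abs=1e-12)
        assert comp.p < 0.05
        assert (1, 3) in comp.pairwise

    def test_identical_groups_not_significant(self):
        x = np.random.default_rng(3).normal(size=40)
        comp = kruskal_dunn(np.concatenate([x, x]), np.repeat([1, 2], 40))
        assert comp.p > 0.9
        assert comp.pairwise == {}

    def test_all_tied_values(self):
        comp = kruskal_dunn(np.ones(30), np.repeat([1, 2, 3], 10))
        assert comp.statistic == 0.0 and comp.p == 1.0

    def test_tie_corrected_statistic_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        values = rng.integers(0, 4, 60).astype(float)  # heavy ties
        labels = np.repeat([1, 2, 3], 20)
        comp = kruskal_dunn(values, labels)
        # direct tie-corrected formula on ranks
        N = len(values)
        ranks = stats.rankdata(values)
        groups = [ranks[labels == c] for c in (1, 2, 3)]
        h = 12 / (N * (N + 1)) * sum(len(g) * g.mean() ** 2 for g in groups) - 3 * (N + 1)
        _, ties = np.unique(values, return_counts=True)
        h /= 1 - (ties**3 - ties).sum() / (N**3 - N)
        assert comp.statistic == pytest.approx(h, rel=1e-12)


class TestContingency:
    def test_drug_row_chi_square_below_printed_bound(self):
        values, labels = binary_fixture(DRUG_COUNTS)
        comp = contingency_test(values, labels)
        assert comp.route == "chi2"
        assert comp.p < 0.0001
        assert comp.pairwise[(1, 2)] < 0.05 and comp.pairwise[(1, 3)] < 0.05

    def test_equal_rates_near_unity_p(self):
        values, labels = binary_fixture(((30, 100), (30, 100), (30, 100)))
        comp = contingency_test(values, labels)
        assert comp.statistic == pytest.approx(0.0, abs=1e-9)
        assert comp.p > 0.99

    def test_fisher_2x2_matches_hypergeometric_enumeration(self):
        """scipy's Fisher exact test is the independent oracle for the
        in-house exact conditional enumeration."""
        table = np.array([[3, 7], [7, 3]])
        oracle = stats.fisher_exact(table).pvalue
        assert exact_conditional_p(table) == pytest.approx(oracle, rel=1e-9)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = rng.integers(0, 12, (2, 2))
            if t.sum(axis=0).min() == 0 or t.sum() == 0:
                continue
            assert exact_conditional_p(t) == pytest.approx(
                stats.fisher_exact(t).pvalue, rel=1e-9
            ), t

    def test_sparse_table_takes_exact_route(self):
        values, labels = binary_fixture(((2, 40), (1, 40), (8, 40)))
        comp = contingency_test(values, labels)
        assert comp.route == "fisher"
        assert 0.0 <= comp.p <= 1.0

    def test_protection_no_pairwise_under_null(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            values = (rng.random(300) < 0.3).astype(float)
            labels = np.repeat([1, 2, 3], 100)
            comp = contingency_test(values, labels)
            if comp.p >= 0.05:
                assert comp.pairwise == {}


class TestLogistic:
    def test_saturated_or_equals_cross_product(self):
        """Cluster-factor logistic is saturated: OR(1 vs 3) must equal the
        2x2 cross-product (84/128) / (44/396)."""
        values, labels = binary_fixture(DRUG_COUNTS)
        comp = logistic_lrt(values, labels)
        assert comp.p < 1e-10
        or13 = comp.odds_ratios[(1, 3)]
        expected = (84 / 128) / (44 / 396)
        assert or13.value == pytest.approx(expected, rel=1e-6)
        assert or13.ci_low < expected < or13.ci_high

    def test_equal_rates_no_pairwise(self):
        values, labels = binary_fixture(((30, 100), (30, 100), (30, 100)))
        comp = logistic_lrt(values, labels)
        assert comp.p > 0.99
        assert comp.odds_ratios == {}

    def test_separation_flagged_unbounded(self):
        values, labels = binary_fixture(((0, 50), (20, 50), (25, 50)))
        comp = logistic_lrt(values, labels)
        assert comp.p < 0.001  # LRT still computed (closed-form saturated LL)
        assert comp.odds_ratios[(1, 2)].unbounded

    def test_lrt_agrees_with_chi_square_on_random_tables(self):
        """Significance agreement at alpha=0.05 on >= 99/100 non-degenerate
        2xk tables with n >= 200."""
        rng = np.random.default_rng(6)
        agree = total = 0
        while total < 100:
            n_per = int(rng.integers(70, 150))
            rates = rng.uniform(0.1, 0.6, 3)
            counts = tuple(
                (int(rng.binomial(n_per, r)), n_per) for r in rates
            )
            if any(c in (0, n_per) for c, _ in counts):
                continue
            values, labels = binary_fixture(counts)
            total += 1
            chi = contingency_test(values, labels)
            lrt = logistic_lrt(values, labels)
            agree += (chi.p < 0.05) == (lrt.p < 0.05)
        assert agree >= 99


class TestDispatchAndProfile:
    def test_binary_outcome_dispatches_to_contingency(self):
        values, labels = binary_fixture(DRUG_COUNTS)
        comp = compare_variable(values, labels, "drugs")
        assert comp.kind == "binary"

    def test_skewed_variable_dispatches_to_kruskal(self):
        rng = np.random.default_rng(7)
        values = rng.lognormal(0, 1, 300)
        labels = np.repeat([1, 2, 3], 100)
        comp = compare_variable(values, labels, "x")
        assert comp.route == "kruskal+dunn"

    def test_profile_reproduces_printed_drug_percentages(self):
        values, labels = binary_fixture(DRUG_COUNTS, sizes=(246, 407, 501))
        table = pd.DataFrame({"drugs_prescribed": values})
        prof = cluster_profile(table, labels, ["drugs_prescribed"])
        assert prof.n_tot["drugs_prescribed"] == 1016
        assert prof.denominators["drugs_prescribed"] == (212, 364, 440)
        assert prof.percentages["drugs_prescribed"] == (39.62, 12.91, 10.0)
        row = prof.formatted.loc["drugs_prescribed"]
        assert row["cluster_1"] == "84 (39.62)"

    def test_profile_handles_fully_missing_outcome(self):
        table = pd.DataFrame({"x": [np.nan] * 9})
        prof = cluster_profile(table, np.repeat([1, 2, 3], 3), ["x"])
        assert prof.n_tot["x"] == 0

    def test_profile_denominators_equal_cluster_sizes_without_missingness(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame({"x": (rng.random(90) < 0.5).astype(float)})
        labels = np.repeat([1, 2, 3], 30)
        prof = cluster_profile(table, labels, ["x"])
        assert prof.denominators["x"] == (30, 30, 30)

    def test_profile_continuous_median_iqr_format(self):
        table = pd.DataFrame({"bmi": np.arange(1.0, 13.0)})
        labels = np.repeat([1, 2], 6)
        prof = cluster_profile(table, labels, ["bmi"])
        assert prof.medians["bmi"] == (3.5, 9.5)
        assert "3.5 (2.25–4.75)" == prof.formatted.loc["bmi", "cluster_1"]
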