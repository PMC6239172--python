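import itertools

import numpy as np
import pandas as pd
import pytest

from primarytx.expression_stats import (
    adjust_fdr,
    adjusted_rand_score,
    kmeans_cluster,
    rank_sum_exact_enumeration,
    rank_sum_test,
    read_through_ratio,
    select_deg,
    summarize_group_metric,
    test_differential_expression as nb_wald_test,
)
from primarytx.synthetic_data import simulate_count_matrix, SyntheticTruth


def nb_counts(rng, mu, n, dispersion=0.05):
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu[:, None]), size=(len(mu), n))


def de(counts_arr, cols_a, cols_b):
    names = [f"l{i}" for i in range(counts_arr.shape[1])]
    counts = pd.DataFrame(counts_arr, columns=names)
    sf = {n: 1.0 for n in names}
    return nb_wald_test(
        counts, sf, [names[i] for i in cols_a], [names[i] for i in cols_b]
    )


class TestDifferentialExpression:
    def test_null_calibration(self, rng):
        """Identical NB groups: p-values roughly uniform (5% below 0.05)."""
        mu = rng.lognormal(np.log(200), 1, 2000)
        table = de(nb_counts(rng, mu, 8), [0, 1, 2, 3], [4, 5, 6, 7])
        frac = (table["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_planted_fourfold_recovered(self, rng):
        mu = rng.lognormal(np.log(200), 1, 500)
        a = nb_counts(rng, mu, 3)
        b = nb_counts(rng, 4 * mu, 3)
        table = de(np.hstack([a, b]), [0, 1, 2], [3, 4, 5])
        assert 1.7 <= table["log2FC"].median() <= 2.3

    def test_all_zero_gene_excluded(self):
        arr = np.array([[0, 0, 0, 0], [5, 6, 4, 7]])
        table = de(arr, [0, 1], [2, 3])
        assert np.isnan(table.loc[0, "p"]) and not np.isnan(table.loc[1, "p"])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            de(np.ones((3, 3), dtype=int), [0], [1, 2])


class TestAdjustFdr:
    def test_single_p_identity(self):
        assert adjust_fdr([0.04])[0] == pytest.approx(0.04)

    def test_step_up_by_hand(self):
        # (m/j)*p_(j) = (0.03, 0.03, 0.03) after the running minimum
        assert adjust_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert adjust_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])

    def test_matches_independent_step_up_oracle(self, rng):
        def bh_oracle(p):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, m / rank * p[i])
                adj[i] = running
            return adj

        p = rng.uniform(size=100)
        assert np.allclose(adjust_fdr(p), bh_oracle(p), atol=1e-12)

    def test_order_invariant_and_dominates_p(self, rng):
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert np.allclose(adjust_fdr(p)[perm], adjust_fdr(p[perm]))
        assert (adjust_fdr(p) >= p - 1e-12).all()

    def test_null_nb_simulation_controls_fdr(self, rng):
        mu = rng.lognormal(np.log(200), 1, 2000)
        table = de(nb_counts(rng, mu, 8), [0, 1, 2, 3], [4, 5, 6, 7])
        padj = adjust_fdr(table["p"])
        assert np.nanmean(padj < 0.01) <= 0.02


class TestSelectDeg:
    @staticmethod
    def result(log2fc, padj):
        return pd.DataFrame({"log2FC": [log2fc], "padj": [padj]}, index=["g1"])

    def test_significant_and_large_fc_selected(self):
        assert select_deg({"c1": self.result(1.5, 0.001)}) == {"g1"}

    def test_small_fc_not_selected_despite_significance(self):
        assert select_deg({"c1": self.result(0.9, 1e-9)}) == set()

    def test_min_contrasts_two_requires_two_hits(self):
        results = {"c1": self.result(1.5, 0.001), "c2": self.result(0.2, 0.9)}
        assert select_deg(results, min_contrasts=2) == set()
        results["c2"] = self.result(-1.4, 0.004)
        assert select_deg(results, min_contrasts=2) == {"g1"}

    def test_no_contrasts_rejected(self):
        with pytest.raises(ValueError):
            select_deg({})


class TestKmeans:
    def test_k1_sse_is_total_scatter(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)))
        _, sse = kmeans_cluster(X, [1], seed=0)
        total = ((X - X.mean()) ** 2).to_numpy().sum()
        assert sse[1] == pytest.approx(total)

    def test_separated_groups_recovered(self, rng):
        centers = np.array([[0, 0], [8, 0], [0, 8]])
        truth = np.repeat([0, 1, 2], 30)
        X = pd.DataFrame(centers[truth] + rng.normal(0, 0.5, size=(90, 2)))
        labels, _ = kmeans_cluster(X, [3], seed=0, select_k=3)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_sse_non_increasing_and_recomputable(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 4)))
        ks = [1, 2, 3, 4, 5]
        sses = []
        for k in ks:
            labels, sse = kmeans_cluster(X, [k], restarts=10, seed=0, select_k=k)
            arr = X.to_numpy()
            recomputed = sum(
                ((arr[labels.to_numpy() == c] - arr[labels.to_numpy() == c].mean(0)) ** 2).sum()
                for c in np.unique(labels)
            )
            assert sse[k] == pytest.approx(recomputed, abs=1e-9 * max(1, recomputed))
            sses.append(sse[k])
        assert all(a >= b - 1e-9 for a, b in zip(sses, sses[1:]))

    def test_k_beyond_genes_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_cluster(pd.DataFrame(rng.normal(size=(3, 2))), [4])


class TestRankSum:
    def test_small_two_sided_exact(self):
        _, p = rank_sum_test([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3, abs=1e-4)

    def test_symmetry_under_swap(self):
        x, y = [1.0, 5.0, 2.5], [4.0, 0.5]
        assert rank_sum_test(x, y)[1] == pytest.approx(rank_sum_test(y, x)[1])

    def test_exact_matches_enumeration_for_all_small_partitions(self):
        """Exact branch equals brute-force enumeration, all tie-free n+m <= 10 splits."""
        for n, m in [(1, 3), (2, 2), (2, 4), (3, 3), (4, 4), (2, 8), (5, 5)]:
            values = list(range(1, n + m + 1))
            for x_idx in itertools.combinations(range(n + m), n):
                x = [values[i] for i in x_idx]
                y = [values[i] for i in range(n + m) if i not in x_idx]
                _, p = rank_sum_test(x, y)
                assert p == pytest.approx(rank_sum_exact_enumeration(x, y), abs=1e-12)

    def test_approximation_close_to_exact_at_n8(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(0.5, size=8)
        _, p_exact = rank_sum_test(x, y)  # n+m=16 still exact
        from scipy import stats

        p_norm = stats.mannwhitneyu(x, y, method="asymptotic").pvalue
        assert abs(p_exact - p_norm) < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestSummaries:
    def test_median_simple(self):
        t = summarize_group_metric({"g": [1, 2, 3]})
        assert t.loc["g", "median"] == 2 and t.loc["g", "n"] == 3

    def test_single_value(self):
        assert summarize_group_metric({"g": [-10.4]}).loc["g", "median"] == -10.4

    def test_quartiles_linear_interpolation(self):
        t = summarize_group_metric({"g": range(1, 9)})
        assert t.loc["g", "Q1"] == pytest.approx(2.75)
        assert t.loc["g", "Q3"] == pytest.approx(6.25)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_group_metric({"g": []})


class TestReadThrough:
    def test_equal_coverage_reads_through(self):
        cov = [100.0] * 20
        ratio, ok = read_through_ratio(cov, (0, 10), (10, 20))
        assert ok and ratio == pytest.approx(1.0)

    def test_premature_termination(self):
        cov = [100.0] * 10 + [25.0] * 10
        ratio, ok = read_through_ratio(cov, (0, 10), (10, 20))
        assert ok and ratio == pytest.approx(0.25)

    def test_zero_leader_flagged_undefined(self):
        cov = [0.0] * 10 + [5.0] * 10
        ratio, ok = read_through_ratio(cov, (0, 10), (10, 20))
        assert not ok and np.isnan(ratio)


class TestGroupingRecovery:
    def test_planted_blocks_recovered_by_deg_plus_kmeans(self):
        """C1-like/C7-like/null blocks: selection plus K-means finds the blocks."""
        counts, design, truth = simulate_count_matrix(SyntheticTruth(), seed=11)
        from primarytx.tss_caller import compute_size_factors

        sf = compute_size_factors(counts.to_numpy(), list(counts.columns))
        results = {}
        ref = [c for c in counts.columns if design.loc[c, "condition"] == "H20"]
        for cond in ("A20", "H10", "A10"):
            cols = [c for c in counts.columns if design.loc[c, "condition"] == cond]
            t = nb_wald_test(counts, sf, ref, cols)
            t["padj"] = adjust_fdr(t["p"])
            results[cond] = t
        degs = sorted(select_deg(results))
        fc = pd.DataFrame({c: t["log2FC"] for c, t in results.items()}).loc[degs]
        labels, _ = kmeans_cluster(fc, [2], seed=0, select_k=2)
        truth_labels = [truth.expression_groups[g] for g in degs]
        # DEGs should be essentially the planted non-null genes
        planted = {g for g, grp in truth.expression_groups.items() if grp != "null"}
        assert len(planted.symmetric_difference(degs)) <= 0.1 * len(planted)
        assert adjusted_rand_score(truth_labels, labels) >= 0.8
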