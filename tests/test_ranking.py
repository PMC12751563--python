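"""Comparison statistics and significant-rank tiering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pepgood.ranking import (PerformanceTable, anova_tukey,
                             assign_significant_ranks, bonferroni,
                             kruskal_wallis, rank_extrapolation_table,
                             rank_interpolation_table, wilcoxon_one_tailed)


def kruskal_oracle(groups):
    """Rank-sum formula with tie correction, computed from first principles."""
    data = np.concatenate(groups)
    n = data.size
    ranks = stats.rankdata(data)
    offset = 0
    h = 0.0
    for g in groups:
        r = ranks[offset:offset + len(g)]
        h += r.sum() ** 2 / len(g)
        offset += len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(data, return_counts=True)
    tie = 1 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / tie


def wilcoxon_exact_oracle(a, b):
    """One-tailed signed-rank p by exhaustive enumeration of sign patterns."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w >= w_obs - 1e-12:
            count += 1
    return count / 2 ** n


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p > 0.9

    def test_fully_separated_groups_maximize_h(self):
        groups = [[1, 2, 3], [101, 102, 103], [201, 202, 203]]
        h, p = kruskal_wallis(groups)
        assert h == pytest.approx(kruskal_oracle(groups))
        assert p < 0.05

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    def test_matches_rank_formula_oracle(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 5))
            groups = [rng.integers(0, 20, size=rng.integers(3, 8)).tolist()
                      for _ in range(k)]
            flat = [v for g in groups for v in g]
            if len(set(flat)) < 2:
                continue
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(kruskal_oracle(groups), abs=1e-8)


class TestWilcoxon:
    def test_all_pairs_greater_exact_p(self):
        a = np.arange(10) + 10.5
        b = np.arange(10).astype(float)
        assert wilcoxon_one_tailed(a, b) == pytest.approx(1 / 2 ** 10)

    def test_equal_samples_warn_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            assert wilcoxon_one_tailed([1., 2, 3, 4, 5], [1., 2, 3, 4, 5]) == 1.0

    def test_opposite_tail(self):
        a = np.arange(10).astype(float)
        b = a + 10.5
        assert wilcoxon_one_tailed(a, b) > 0.999

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            wilcoxon_one_tailed([1., 2, 3, 4, 5], [1., 2, 3])

    def test_matches_enumeration_oracle(self, rng):
        checked = 0
        while checked < 150:
            n = int(rng.integers(5, 13))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            d = np.abs(a - b)
            if len(set(d)) < n or np.any(d == 0):
                continue
            p = wilcoxon_one_tailed(a, b)
            assert p == pytest.approx(wilcoxon_exact_oracle(a, b), abs=1e-10)
            checked += 1


class TestAnovaTukey:
    def test_identical_groups_not_significant(self):
        groups = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.1, 2.1, 2.9, 4.0]}
        _, p, pairwise = anova_tukey(groups)
        assert p > 0.5
        assert pairwise[("a", "b")] > 0.5

    def test_separated_tight_groups(self):
        groups = {"lo": [0.0, 0.01, 0.02, 0.01], "hi": [5.0, 5.01, 5.02, 4.99]}
        _, p, pairwise = anova_tukey(groups)
        assert pairwise[("lo", "hi")] < 1e-6

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1, 2, 3]})

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = {f"g{i}": rng.normal(i * rng.random(), 1, size=6)
                      for i in range(k)}
            _, _, pairwise = anova_tukey(groups)
            values = np.concatenate([groups[f"g{i}"] for i in range(k)])
            labels = np.repeat([f"g{i}" for i in range(k)], 6)
            ref = pairwise_tukeyhsd(values, labels)
            names = list(ref.groupsunique)
            ref_pairs = list(itertools.combinations(names, 2))
            for (g1, g2), padj in zip(ref_pairs, ref.pvalues):
                assert pairwise[(str(g1), str(g2))] == pytest.approx(
                    float(padj), abs=1e-6)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected",
                             [(0.05, 1, 0.05), (0.05, 12, 0.05 / 12),
                              (0.05, 10, 0.005)])
    def test_corrected_threshold(self, alpha, m, expected):
        assert bonferroni(alpha, m) == pytest.approx(expected)

    def test_twelve_comparisons_match_printed_cutoff(self):
        # 12 pairwise comparisons: 0.05/12 ~ 0.004
        assert bonferroni(0.05, 12) == pytest.approx(0.004167, abs=1e-6)

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)


class TestSignificantRanks:
    means3 = {"a": 0.9, "b": 0.8, "c": 0.7}

    def pairwise(self, sig_pairs):
        p = {}
        for x in self.means3:
            for y in self.means3:
                if x != y:
                    p[(x, y)] = 0.001 if (x, y) in sig_pairs else 0.5
        return p

    def test_all_significant_gives_ranks_1_to_n(self):
        p = self.pairwise({("a", "b"), ("a", "c"), ("b", "c")})
        ranks = assign_significant_ranks(self.means3, p, 0.01).ranks()
        assert ranks == {"a": 1, "b": 2, "c": 3}

    def test_none_significant_all_rank_one(self):
        ranks = assign_significant_ranks(self.means3, self.pairwise(set()),
                                         0.01).ranks()
        assert ranks == {"a": 1, "b": 1, "c": 1}

    def test_comparison_is_with_rank_head(self):
        # (a,b) not significant, (a,c) significant -> {1, 1, 2} even though
        # b vs c was never consulted
        p = self.pairwise({("a", "c")})
        ranks = assign_significant_ranks(self.means3, p, 0.01).ranks()
        assert ranks == {"a": 1, "b": 1, "c": 2}

    def test_order_invariance(self, rng):
        reps = [f"r{i}" for i in range(6)]
        for _ in range(100):
            means = {r: float(rng.random()) for r in reps}
            p = {}
            for x in reps:
                for y in reps:
                    if x != y:
                        p[(x, y)] = float(rng.random() * 0.2)
            baseline = assign_significant_ranks(means, p, 0.05).ranks()
            shuffled_means = dict(
                (k, means[k]) for k in rng.permutation(reps))
            assert assign_significant_ranks(shuffled_means, p,
                                            0.05).ranks() == baseline

    def test_missing_pair_raises(self):
        with pytest.raises(KeyError):
            assign_significant_ranks({"a": 1.0, "b": 0.5}, {}, 0.05)


class TestTablePipelines:
    def make_table(self, shift=0.3, n_units=12, rng=None):
        rng = rng or np.random.default_rng(0)
        rows = []
        for rep, mu in [("good", shift), ("bad", 0.0)]:
            for u in range(n_units):
                rows.append({"representation": rep, "dataset": "d",
                             "threshold": 0.1 * (u % 4), "seed": u // 4,
                             "metric": float(np.clip(
                                 mu + rng.normal(0, 0.05), -1, 1))})
        return PerformanceTable(pd.DataFrame(rows),
                                unit_columns=("dataset", "threshold", "seed"))

    def test_interpolation_ranks_separate_clear_winner(self):
        ranks, info = rank_interpolation_table(self.make_table(shift=0.4))
        assert info["gate"] == "passed"
        assert ranks.ranks()["good"] == 1
        assert ranks.ranks()["bad"] == 2

    def test_unpaired_design_rejected(self):
        df = pd.DataFrame([
            {"representation": "a", "dataset": "d", "threshold": 0.1,
             "seed": 0, "metric": 0.5},
            {"representation": "b", "dataset": "d", "threshold": 0.2,
             "seed": 0, "metric": 0.5},
        ])
        with pytest.raises(ValueError, match="unpaired"):
            PerformanceTable(df, unit_columns=("dataset", "threshold", "seed"))

    def test_extrapolation_pipeline(self):
        rng = np.random.default_rng(1)
        rows = []
        for rep, mu in [("x", 0.5), ("y", 0.1)]:
            for run in range(25):
                rows.append({"representation": rep, "dataset": "d",
                             "run": run, "metric": mu + rng.normal(0, 0.05)})
        table = PerformanceTable(pd.DataFrame(rows),
                                 unit_columns=("dataset", "run"))
        ranks, info = rank_extrapolation_table(table)
        assert ranks.ranks() == {"x": 1, "y": 2}
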