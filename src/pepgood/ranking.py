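"""Model-comparison statistics and significant-rank tiering.

Interpolation tables (many paired splits per representation) are compared
with a Kruskal-Wallis gate followed by pairwise one-tailed Wilcoxon
signed-rank tests under a Bonferroni-corrected threshold; extrapolation
tables use one-way ANOVA with Tukey's HSD (already multiplicity-adjusted).
Representations are then tiered into *significant ranks*: walking down the
mean-performance ordering, a representation joins the current rank when it
is not significantly worse than the rank's first (best) member, and opens
the next rank otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PerformanceTable:
    """Long-format paired results: one metric value per
    (representation, experiment unit)."""

    frame: pd.DataFrame  # columns: representation, unit, metric
    unit_columns: Tuple[str, ...] = ("dataset", "threshold", "seed")

    def __post_init__(self):
        needed = {"representation", "metric"} | set(self.unit_columns)
        missing = needed - set(self.frame.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")
        units_per_rep = self.frame.groupby("representation")[
            list(self.unit_columns)].apply(
                lambda df: frozenset(map(tuple, df.to_numpy())))
        if len(set(units_per_rep)) > 1:
            raise ValueError("representations do not share experiment units "
                             "(unpaired design)")

    def representations(self) -> List[str]:
        return sorted(self.frame["representation"].unique())

    def values_by_representation(self) -> Dict[str, np.ndarray]:
        """Metric vectors aligned on the shared experiment-unit ordering."""
        cols = list(self.unit_columns)
        out = {}
        for rep, df in self.frame.groupby("representation"):
            out[rep] = df.sort_values(cols)["metric"].to_numpy()
        return out

    def means(self) -> Dict[str, float]:
        return self.frame.groupby("representation")["metric"].mean().to_dict()

    def sds(self) -> Dict[str, float]:
        return self.frame.groupby("representation")["metric"].std().to_dict()


@dataclass
class RankTable:
    """Per-representation mean, sd and significant-rank assignment."""

    rows: List[Dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def ranks(self) -> Dict[str, int]:
        return {r["representation"]: r["rank"] for r in self.rows}


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-squared p-value."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def wilcoxon_one_tailed(a: Sequence[float], b: Sequence[float]) -> float:
    """One-tailed (a > b) Wilcoxon signed-rank p-value on paired values.

    Zero differences are discarded; the p-value is exact (permutation
    distribution, midranks under ties) for n <= 25, otherwise a
    tie-corrected normal approximation with continuity correction is used.
    All-zero differences give p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(a, b, alternative="greater", zero_method="wilcox",
                         method=method, correction=(method == "approx"))
    return float(res.pvalue)


def anova_tukey(groups: Dict[str, Sequence[float]]
                ) -> Tuple[float, float, Dict[Tuple[str, str], float]]:
    """One-way ANOVA F and p plus Tukey-HSD adjusted pairwise p-values."""
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    data = [np.asarray(groups[n], dtype=float) for n in names]
    if any(g.size < 2 for g in data):
        raise ValueError("each group needs at least 2 values")
    if all(np.all(g == data[0][0]) for g in data):
        raise ValueError("degenerate: all values identical")
    f, p = stats.f_oneway(*data)
    res = stats.tukey_hsd(*data)
    pairwise = {}
    for i, ni in enumerate(names):
        for j, nj in enumerate(names):
            if i < j:
                pv = float(res.pvalue[i, j])
                pairwise[(ni, nj)] = pv
                pairwise[(nj, ni)] = pv
    return float(f), float(p), pairwise


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def assign_significant_ranks(means: Dict[str, float],
                             pairwise_p: Dict[Tuple[str, str], float],
                             alpha_corrected: float,
                             sds: Dict[str, float] | None = None) -> RankTable:
    """Tier representations into significant ranks.

    Representations are sorted by descending mean.  Each is compared with
    the *first* member of the current rank: p(first > current) below the
    corrected threshold opens a new rank, otherwise the representation
    joins the current one.  ``pairwise_p[(x, y)]`` is the p-value of the
    one-tailed test "x better than y".
    """
    order = sorted(means, key=lambda r: (-means[r], r))
    rows = []
    rank = 1
    rank_head = order[0]
    for rep in order:
        if rep != rank_head:
            key = (rank_head, rep)
            if key not in pairwise_p:
                raise KeyError(f"missing pairwise p-value for {key}")
            if pairwise_p[key] < alpha_corrected:
                rank += 1
                rank_head = rep
        rows.append({"representation": rep, "mean": means[rep],
                     "sd": (sds or {}).get(rep, float("nan")), "rank": rank})
    return RankTable(rows)


def rank_interpolation_table(table: PerformanceTable, alpha: float = 0.05
                             ) -> Tuple[RankTable, Dict]:
    """Kruskal-Wallis gate, pairwise one-tailed Wilcoxon with Bonferroni,
    then significant-rank assignment."""
    by_rep = table.values_by_representation()
    reps = sorted(by_rep)
    h, p_kw = kruskal_wallis([by_rep[r] for r in reps])
    means = table.means()
    sds = table.sds()
    m = len(reps) * (len(reps) - 1) // 2
    alpha_c = bonferroni(alpha, m)
    if p_kw >= alpha:
        rows = [{"representation": r, "mean": means[r], "sd": sds[r], "rank": 1}
                for r in sorted(means, key=lambda r: (-means[r], r))]
        return RankTable(rows), {"kruskal_H": h, "kruskal_p": p_kw,
                                 "alpha_corrected": alpha_c, "gate": "failed"}
    pairwise = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, ri in enumerate(reps):
            for rj in reps[i + 1:]:
                pairwise[(ri, rj)] = wilcoxon_one_tailed(by_rep[ri], by_rep[rj])
                pairwise[(rj, ri)] = wilcoxon_one_tailed(by_rep[rj], by_rep[ri])
    ranks = assign_significant_ranks(means, pairwise, alpha_c, sds)
    return ranks, {"kruskal_H": h, "kruskal_p": p_kw,
                   "alpha_corrected": alpha_c, "gate": "passed"}


def rank_extrapolation_table(table: PerformanceTable, alpha: float = 0.05
                             ) -> Tuple[RankTable, Dict]:
    """ANOVA + Tukey HSD (no extra correction), then significant ranks."""
    by_rep = table.values_by_representation()
    f, p, pairwise = anova_tukey(by_rep)
    ranks = assign_significant_ranks(table.means(), pairwise, alpha, table.sds())
    return ranks, {"anova_F": f, "anova_p": p, "alpha": alpha}
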