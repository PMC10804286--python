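"""Crossover-design deltas and exact nonparametric tests.

Within-animal treatment effects in a randomized crossover design are
per-subject deltas (condition2 - condition1); the Wilcoxon matched-pairs
signed-rank test compares them against zero within a group, and the
Mann-Whitney (rank-sum) test compares deltas between groups.  Both tests
are *exact* for the small group sizes typical of animal studies: the full
permutation null distribution — all 2^n sign assignments, or all
C(n_a+n_b, n_a) group labelings — is computed by dynamic programming over
(doubled, hence integer) mid-ranks, which is algebraically identical to
full enumeration but feasible up to n = 25 / n_a+n_b = 20.  Ties are
handled by mid-ranks in both the statistic and its null distribution.
Larger samples fall back to the normal approximation with continuity and
tie corrections, flagged in the result.

Two-sided p-values are twice the smaller tail probability, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, norm

__all__ = [
    "TestResult",
    "PairedDesign",
    "wilcoxon_signed_rank_exact",
    "mann_whitney_exact",
    "boxplot_summary",
    "BoxplotSummary",
]

WILCOXON_EXACT_MAX_N = 25
MANN_WHITNEY_EXACT_MAX_N = 20


@dataclass
class TestResult:
    statistic: float
    p_value: float            # two-sided
    p_one_sided: float        # smaller tail
    n: int
    method: str               # "exact" | "normal-approximation" | "degenerate"


@dataclass
class PairedDesign:
    """Per-subject outcomes under two crossover conditions."""

    subjects: list[str]
    condition_a: str
    condition_b: str
    values_a: list[float]
    values_b: list[float]

    def __post_init__(self) -> None:
        if len(self.subjects) != len(set(self.subjects)):
            raise ValueError("each subject must appear exactly once per condition")
        if not (len(self.subjects) == len(self.values_a) == len(self.values_b)):
            raise ValueError("subjects and both value lists must align")

    @property
    def deltas(self) -> np.ndarray:
        """condition_b - condition_a per subject."""
        return np.asarray(self.values_b, dtype=float) - np.asarray(self.values_a, dtype=float)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, subject: str, condition: str, value: str,
        condition_a: str, condition_b: str,
    ) -> "PairedDesign":
        wide = df.pivot(index=subject, columns=condition, values=value)
        if condition_a not in wide or condition_b not in wide:
            raise ValueError("both conditions must be present")
        wide = wide.dropna(subset=[condition_a, condition_b])
        return cls(
            subjects=[str(s) for s in wide.index],
            condition_a=condition_a,
            condition_b=condition_b,
            values_a=list(wide[condition_a]),
            values_b=list(wide[condition_b]),
        )


def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Counts of each doubled signed-rank sum over all 2^n sign assignments."""
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank_exact(deltas) -> TestResult:
    """Exact Wilcoxon matched-pairs signed-rank test of deltas against zero.

    W is the sum of the (mid-)ranks of |delta| carried by positive deltas;
    zero deltas are dropped first.  Exact up to n = 25; all-zero deltas
    give the degenerate result p = 1.
    """
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, 1.0, 0, "degenerate")
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= WILCOXON_EXACT_MAX_N:
        dr = np.round(2 * ranks).astype(int)
        counts = _signed_rank_distribution(dr)
        total = counts.sum()
        w2 = int(round(2 * w))
        p_ge = counts[w2:].sum() / total
        p_le = counts[: w2 + 1].sum() / total
        p_one = min(p_ge, p_le)
        return TestResult(w, min(1.0, 2.0 * p_one), p_one, n, "exact")
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w - mu - 0.5 * np.sign(w - mu)) / np.sqrt(var)
    p_one = float(norm.sf(abs(z)))
    return TestResult(w, min(1.0, 2.0 * p_one), p_one, n, "normal-approximation")


def _rank_sum_distribution(double_ranks: np.ndarray, n_a: int) -> np.ndarray:
    """Counts of each doubled rank sum over all C(N, n_a) group-A labelings."""
    total = int(double_ranks.sum())
    # dp[k, s]: labelings choosing k ranks with doubled sum s
    dp = np.zeros((n_a + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in double_ranks:
        r = int(r)
        # numpy buffers overlapping in-place ufunc operands, so every row
        # update uses the pre-item counts: each rank is taken at most once
        dp[1:, r:] += dp[:-1, : total + 1 - r]
    return dp[n_a]


def mann_whitney_exact(group_a, group_b) -> TestResult:
    """Exact Mann-Whitney test between two independent groups.

    U = R_a - n_a(n_a+1)/2 with R_a the (mid-)rank sum of group A in the
    pooled sample.  Exact for n_a + n_b <= 20, normal approximation with
    tie correction beyond.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    ranks = rankdata(np.concatenate([a, b]))
    r_a = float(ranks[:n_a].sum())
    u = r_a - n_a * (n_a + 1) / 2.0
    if n <= MANN_WHITNEY_EXACT_MAX_N:
        dr = np.round(2 * ranks).astype(int)
        counts = _rank_sum_distribution(dr, n_a)
        total = counts.sum()
        r2 = int(round(2 * r_a))
        p_ge = counts[r2:].sum() / total
        p_le = counts[: r2 + 1].sum() / total
        p_one = min(p_ge, p_le)
        return TestResult(u, min(1.0, 2.0 * p_one), p_one, n, "exact")
    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n_a * n_b / 12.0 * (n + 1 - tie_term)
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var)
    p_one = float(norm.sf(abs(z)))
    return TestResult(u, min(1.0, 2.0 * p_one), p_one, n, "normal-approximation")


@dataclass
class BoxplotSummary:
    """Tukey boxplot statistics: median, quartiles, 1.5*IQR whiskers, outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float] = field(default_factory=list)

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def boxplot_summary(values) -> BoxplotSummary:
    """Boxplot statistics with linearly interpolated quartiles.

    Whiskers extend to the most extreme data point within 1.5*IQR of the
    nearer quartile; points beyond are listed as outliers.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("boxplot_summary needs at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    whisker_low = float(inside.min()) if inside.size else float(med)
    whisker_high = float(inside.max()) if inside.size else float(med)
    outliers = [float(x) for x in v[(v < lo_fence) | (v > hi_fence)]]
    return BoxplotSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_low=whisker_low, whisker_high=whisker_high, outliers=outliers,
    )
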