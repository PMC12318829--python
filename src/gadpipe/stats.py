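"""Core statistical procedures: Pearson correlation and the two-sided
Wilcoxon rank-sum test.

Both are implemented here rather than delegated, so that every p-value the
pipeline reports is produced by one auditable code path.  The rank-sum test
switches between exact enumeration (small, tie-free samples) and a
tie-corrected normal approximation with continuity correction; the method
used is recorded in every result.

No multiple-testing correction is applied anywhere in this package: all
thresholds downstream are on raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm as _norm
from scipy.stats import rankdata
from scipy.stats import t as _t_dist

__all__ = ["CorrResult", "RankSumResult", "pearson", "ranksum"]

#: largest size of the smaller group for which the exact rank-sum
#: distribution is enumerated (tie-free samples only).
EXACT_MAX_N = 8


@dataclass(frozen=True)
class CorrResult:
    """Pearson correlation with its two-sided p-value."""

    r: float
    p: float
    n: int


@dataclass(frozen=True)
class RankSumResult:
    """Two-sided Wilcoxon rank-sum test result.

    ``statistic`` is the rank-sum of the first sample.  ``method`` is
    ``"exact"`` (full enumeration of rank assignments) or
    ``"normal_tie_corrected"``.
    """

    statistic: float
    p: float
    method: str
    n1: int
    n2: int


def pearson(x, y) -> CorrResult:
    """Product-moment correlation with a two-sided p-value.

    The p-value comes from the exact null distribution of
    ``t = r * sqrt(n - 2) / sqrt(1 - r**2)``, which is Student-t with
    ``n - 2`` degrees of freedom under bivariate normality.  ``|r| = 1``
    returns ``p = 0``.

    Raises ``ValueError`` on length mismatch, ``n < 3`` or a constant
    input vector (the correlation is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError(
            f"pearson requires two equal-length vectors, got {x.size} and {y.size}"
        )
    n = x.size
    if n < 3:
        raise ValueError(f"pearson requires n >= 3 samples, got {n}")
    xd = x - x.mean()
    yd = y - y.mean()
    sxx = float(xd @ xd)
    syy = float(yd @ yd)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("correlation undefined: constant input vector")
    r = float(xd @ yd) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * _t_dist.sf(abs(t), n - 2))
    return CorrResult(r=r, p=min(p, 1.0), n=n)


def _exact_ranksum_counts(k: int, n_total: int) -> np.ndarray:
    """Distribution of the rank-sum of a k-subset of ranks 1..n_total.

    Returns ``counts`` where ``counts[s]`` is the number of k-subsets of
    {1, ..., n_total} whose elements sum to ``s``.  Dynamic program
    equivalent to enumerating all C(n_total, k) assignments.
    """
    max_sum = k * (2 * n_total - k + 1) // 2
    dp = np.zeros((k + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for r in range(1, n_total + 1):
        for j in range(min(r, k), 0, -1):
            dp[j, r:] += dp[j - 1, : max_sum + 1 - r]
    return dp[k]


def ranksum(a, b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p by enumeration of all rank assignments when the smaller group
    has at most ``EXACT_MAX_N`` observations and there are no ties;
    otherwise a normal approximation on midranks with tie-corrected
    variance and a 0.5 continuity correction.  The exact two-sided p is
    ``2 * min(P(W <= w), P(W >= w))`` capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError(f"ranksum requires non-empty groups, got n1={n1}, n2={n2}")
    if n1 + n2 < 3:
        raise ValueError("ranksum requires n1 + n2 >= 3")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    w = float(ranks[:n1].sum())
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if min(n1, n2) <= EXACT_MAX_N and not has_ties:
        # distribution of the smaller group's rank-sum; two-sided p is the
        # same computed on either group since W1 + W2 = n(n+1)/2
        if n1 <= n2:
            k, wk = n1, w
        else:
            k, wk = n2, float(ranks[n1:].sum())
        counts = _exact_ranksum_counts(k, n)
        total = counts.sum()
        wi = int(round(wk))
        p_le = counts[: wi + 1].sum() / total
        p_ge = counts[wi:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return RankSumResult(statistic=w, p=float(p), method="exact", n1=n1, n2=n2)

    mu = n1 * (n + 1) / 2.0
    tie_term = float((tie_counts.astype(float) ** 3 - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0.0:
        # all pooled values identical
        return RankSumResult(
            statistic=w, p=1.0, method="normal_tie_corrected", n1=n1, n2=n2
        )
    d = w - mu
    d_cc = d - 0.5 * np.sign(d)  # continuity correction toward the mean
    z = d_cc / np.sqrt(var)
    p = min(1.0, float(2.0 * _norm.sf(abs(z))))
    return RankSumResult(
        statistic=w, p=p, method="normal_tie_corrected", n1=n1, n2=n2
    )
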