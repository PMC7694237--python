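"""Paired nonparametric arm comparison: the Wilcoxon signed-rank test.

The small samples here (24 institutions per arm) sit exactly where the
normal approximation is weakest, so the test uses the exact null
distribution of W — the sum of positive-signed ranks — whenever the
differences are tie-free and n is small enough. The exact distribution is
built by dynamic programming over sign assignments (the distribution of
``sum(ranks of positive d)`` under 2^n equiprobable sign vectors), which is
identical to full enumeration. With ties, midranks are used and the test
falls back to a tie-corrected normal approximation with continuity
correction; the result records which route was taken.

An unpaired rank-sum comparison (used for the IMN-inclusion subgroup
contrast) is delegated to :func:`scipy.stats.mannwhitneyu`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["PairedTestResult", "wilcoxon_signed_rank", "rank_sum_test"]


@dataclass
class PairedTestResult:
    statistic: float  # W: sum of positive-signed ranks
    n_effective: int  # pairs with non-zero difference
    p_value: float
    method: str  # "exact" | "normal-approximation"
    alternative: str = "two-sided"


def _exact_w_distribution(ranks: np.ndarray) -> np.ndarray:
    """Counts of each achievable W over all 2^n sign assignments.

    ``ranks`` must be positive integers; returns an array c where c[w] is
    the number of sign vectors with sum of positive ranks equal to w.
    Counts stay below 2^53 for n <= 25, so float64 arithmetic is exact.
    """
    total = int(np.sum(ranks))
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    zero_policy: str = "drop",
    alternative: str = "two-sided",
    exact_max_n: int = 25,
) -> PairedTestResult:
    """Wilcoxon signed-rank test on paired samples ``x`` and ``y``.

    Differences d = x - y; zero differences are dropped by default
    (Wilcoxon's original policy) or kept for ranking and then discarded
    from W under ``zero_policy="pratt"``. Exact two-sided p-values by full
    enumeration of sign assignments when the non-zero differences are
    tie-free and n_effective <= ``exact_max_n``; otherwise a tie-corrected
    normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D sequences of equal length")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if zero_policy not in ("drop", "pratt"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    d = x - y
    nonzero = d != 0
    if not nonzero.any():
        raise ValueError("all paired differences are zero; test undefined")

    if zero_policy == "drop":
        d_used = d[nonzero]
        ranks = sps.rankdata(np.abs(d_used))
    else:  # pratt: rank zeros too, then drop them from the statistic
        ranks_all = sps.rankdata(np.abs(d))
        d_used = d[nonzero]
        ranks = ranks_all[nonzero]
    n_eff = d_used.size
    if n_eff < 3:
        raise ValueError("need at least 3 non-zero paired differences")
    W = float(ranks[d_used > 0].sum())

    has_ties = np.unique(np.abs(d_used)).size != n_eff
    use_exact = (not has_ties) and zero_policy == "drop" and n_eff <= exact_max_n

    if use_exact:
        int_ranks = np.rint(ranks).astype(int)
        counts = _exact_w_distribution(int_ranks)
        total = counts.sum()  # == 2**n_eff
        w_int = int(round(W))
        cdf = counts[: w_int + 1].sum() / total
        sf = counts[w_int:].sum() / total  # P(W >= w)
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(cdf, sf))
        elif alternative == "greater":
            p = sf
        else:
            p = cdf
        return PairedTestResult(W, n_eff, float(p), "exact", alternative)

    # normal approximation with tie correction and continuity correction
    mean = n_eff * (n_eff + 1) / 4.0
    _, t_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((t_counts**3 - t_counts) / 48.0).sum())
    var = n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0 - tie_term
    if var <= 0:
        raise ValueError("degenerate variance in signed-rank approximation")
    sd = np.sqrt(var)
    if alternative == "two-sided":
        z = (W - mean - 0.5 * np.sign(W - mean)) / sd
        p = 2.0 * sps.norm.sf(abs(z))
    elif alternative == "greater":
        z = (W - mean - 0.5) / sd
        p = sps.norm.sf(z)
    else:
        z = (W - mean + 0.5) / sd
        p = sps.norm.cdf(z)
    return PairedTestResult(W, n_eff, float(min(1.0, p)), "normal-approximation", alternative)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided unpaired rank-sum (Mann-Whitney) p-value for two groups."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
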