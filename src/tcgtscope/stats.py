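"""Exact statistics shared by every enrichment and comparison step.

All enrichment tests in this package are one-sided toward over-representation
(the hypergeometric and binomial tails), while the Fisher and rank-sum
comparisons are two-sided.  P-value families are corrected with the
Benjamini-Hochberg step-up procedure; the caller decides which p-values form
one family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sps


@dataclass
class PValueVector:
    """A family of p-values with parallel unique labels."""

    values: list[float]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.labels):
            raise ValueError(
                f"values ({len(self.values)}) and labels ({len(self.labels)}) differ in length"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        for lab, v in zip(self.labels, self.values):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"p-value for {lab!r} outside [0,1]: {v}")

    def __len__(self) -> int:
        return len(self.values)


def hypergeom_sf(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Drawing ``n`` items without replacement from a population of ``N``
    containing ``K`` successes, returns the probability of observing ``k``
    or more successes.

    Parameters
    ----------
    k : successes observed in the sample
    K : successes in the population
    n : sample size
    N : population size
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K <= N and 0 <= n <= N, got k={k} K={K} n={n} N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n), got k={k} K={K} n={n} N={N}")
    # sf(k-1) == P(X >= k)
    return float(_sps.hypergeom.sf(k - 1, N, K, n))


def binom_sf(k: int, n: int, p0: float) -> float:
    """One-sided exact binomial upper tail P(X >= k) with X ~ Bin(n, p0)."""
    if not (0.0 <= p0 <= 1.0):
        raise ValueError(f"p0 outside [0,1]: {p0}")
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k} n={n}")
    return float(_sps.binom.sf(k - 1, n, p0))


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Sums, with margins fixed, the probabilities of all tables whose
    probability does not exceed that of the observed table.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError(f"negative cell in table {t.tolist()}")
    if t.sum() == 0:
        raise ValueError("all margins are zero")
    return float(_sps.fisher_exact(t, alternative="two-sided")[1])


def bh_adjust(pvals: PValueVector) -> PValueVector:
    """Benjamini-Hochberg step-up adjustment, capped at 1, label order kept."""
    p = np.asarray(pvals.values, dtype=float)
    m = p.size
    if m == 0:
        return PValueVector([], [])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return PValueVector(out.tolist(), list(pvals.labels))


@dataclass
class RankSumResult:
    """Two-sided Wilcoxon rank-sum outcome.

    ``method`` records which branch produced the p-value: ``"exact"``
    (full null distribution of the Mann-Whitney U, tie-free samples with
    at most 12 observations in total) or ``"normal"`` (tie-corrected
    normal approximation, no continuity correction).
    """

    statistic: float  # Mann-Whitney U of the first sample
    pvalue: float
    method: str
    medians: tuple[float, float] = field(default=(np.nan, np.nan))


def ranksum_test(a: Sequence[float], b: Sequence[float], exact_limit: int = 12) -> RankSumResult:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    Exact by enumeration of the U null distribution when the pooled sample
    has at most ``exact_limit`` observations and no ties; otherwise a normal
    approximation with the standard tie correction of the variance.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    medians = (float(np.median(x)), float(np.median(y)))

    if pooled.size <= exact_limit and not has_ties:
        res = _sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return RankSumResult(float(res.statistic), float(res.pvalue), "exact", medians)

    # Normal approximation with midranks and tie-corrected variance.
    n1, n2 = x.size, y.size
    ranks = _sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    nt = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((nt + 1) - tie_term / (nt * (nt - 1)))
    if var <= 0:  # all values identical
        return RankSumResult(float(u1), 1.0, "normal", medians)
    z = (u1 - mu) / np.sqrt(var)
    p = min(1.0, 2.0 * float(_sps.norm.sf(abs(z))))
    return RankSumResult(float(u1), p, "normal", medians)
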