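"""Exact and approximate tests shared by the pipeline.

Fisher's exact test uses the point-probability (minimum-likelihood) definition
of the two-sided p value — the sum of hypergeometric probabilities of all
tables with the observed margins whose probability does not exceed the
observed table's — which is the convention of the R ecosystem this analysis
style comes from. The Wilcoxon rank-sum test enumerates the exact null for
small samples (midranks, so ties are handled) and otherwise uses the
tie-corrected normal approximation with continuity correction.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import stats as sps

from .core import ValidationError

_REL_EPS = 1e-7  # relative tolerance when comparing table probabilities


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise ValidationError("table cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        raise ValidationError("all table margins must be positive")
    dist = sps.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    probs = dist.pmf(support)
    p_obs = dist.pmf(a)
    p = probs[probs <= p_obs * (1 + _REL_EPS)].sum()
    return float(min(1.0, p))


def odds_ratio(a: int, b: int, c: int, d: int, haldane: bool = True) -> float:
    """Sample odds ratio; Haldane 0.5 correction when any cell is zero."""
    if min(a, b, c, d) == 0 and haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        return float("inf")
    return (a * d) / (b * c)


def _rank_sum_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by full enumeration over group assignments (midranks)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks handle ties
    n, m = len(x), len(y)
    obs = ranks[:n].sum()
    total = comb(n + m, n)
    center = ranks.sum() * n / (n + m)
    dev = abs(obs - center)
    hits = 0
    for idx in combinations(range(n + m), n):
        if abs(ranks[list(idx)].sum() - center) >= dev - 1e-12:
            hits += 1
    return hits / total


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U (for ``x``) and the two-sided p value.

    ``mode='auto'`` enumerates the exact null when the pooled size is <= 20,
    otherwise uses the tie-corrected normal approximation with continuity
    correction. ``'exact'`` and ``'normal'`` force a method.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    n, m = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    rank_sum_x = ranks[:n].sum()
    u = rank_sum_x - n * (n + 1) / 2

    if mode not in ("auto", "exact", "normal"):
        raise ValidationError("mode must be auto, exact or normal")
    use_exact = mode == "exact" or (mode == "auto" and n + m <= 20)
    if use_exact:
        return float(u), float(_rank_sum_exact(x, y))

    mean_u = n * m / 2
    # tie correction on the null variance
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var_u = n * m / 12 * ((n + m + 1) - tie_term / ((n + m) * (n + m - 1)))
    if var_u == 0:
        return float(u), 1.0
    z = (abs(u - mean_u) - 0.5) / sqrt(var_u)  # continuity correction
    p = 2 * sps.norm.sf(max(z, 0.0))
    return float(u), float(min(1.0, p))


def replicate_pearson(counts_rep1, counts_rep2, pseudocount: float = 1.0) -> float:
    """Pearson r of log2(count + pseudocount) between two replicates."""
    c1 = np.asarray(counts_rep1, dtype=float)
    c2 = np.asarray(counts_rep2, dtype=float)
    if c1.shape != c2.shape or c1.size < 3:
        raise ValidationError("replicate vectors must have equal length >= 3")
    if np.any(c1 + pseudocount <= 0) or np.any(c2 + pseudocount <= 0):
        raise ValidationError("counts + pseudocount must be positive")
    l1, l2 = np.log2(c1 + pseudocount), np.log2(c2 + pseudocount)
    if l1.std() == 0 or l2.std() == 0:
        raise ValidationError("zero variance in a replicate")
    return float(np.corrcoef(l1, l2)[0, 1])
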