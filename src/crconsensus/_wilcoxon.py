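"""Exact one-sided Wilcoxon signed-rank p-values.

Detection and change calls both reduce to a one-sided signed-rank test on a
short vector of paired differences (typically 11-20 probe pairs).  At these
sample sizes the normal approximation is poor in the extreme tails that the
call thresholds live in (p <= 0.0025), so the exact conditional null
distribution of the positive-rank sum W+ is computed instead: conditional on
the observed magnitudes (ties kept, mid-ranks), every one of the 2^n sign
assignments is equally likely under H0.  The distribution is obtained by
dynamic programming over the (doubled, hence integer) ranks, which is
equivalent to full sign-assignment enumeration but costs O(n * sum(ranks)).

Two tail conventions are provided:

* plain  — p = P(W+ >= w);   used for detection calls.
* mid-p  — p = P(W+ > w) + 0.5 * P(W+ = w); used for change calls, so that
  swapping baseline and experiment maps p exactly to 1 - p and a fully
  symmetric comparison sits at p = 0.5.

Above ``exact_limit`` observations a normal approximation with tie
correction is used (with a 0.5 continuity correction for the plain tail,
none for mid-p, which is already centred).
"""

from __future__ import annotations

import functools

import numpy as np
from scipy.stats import norm, rankdata

#: Largest n for which the exact null distribution is used.
DEFAULT_EXACT_LIMIT = 25


@functools.lru_cache(maxsize=8192)
def _null_counts(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Counts of sign assignments by doubled rank-sum W2 = 2*W+.

    ``counts[s]`` is the number of the 2^n sign assignments whose positive
    doubled-rank sum equals ``s``.  Counts are exact in float64 for n <= 25
    (max count 2^25).
    """
    total = sum(doubled_ranks)
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts += shifted
    return counts


def signed_rank_p(
    diffs: np.ndarray,
    *,
    mid_p: bool = False,
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> float:
    """One-sided p for H1: the differences tend to be positive.

    Zero differences must already have been removed by the caller (each
    caller owns its all-zero convention).  Tied magnitudes receive mid-ranks
    and the exact distribution is conditioned on the observed rank multiset.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("need a non-empty 1-D vector of non-zero differences")
    if np.any(d == 0):
        raise ValueError("zero differences must be dropped before testing")
    ranks = rankdata(np.abs(d))
    doubled = np.rint(2.0 * ranks).astype(int)
    w2 = int(doubled[d > 0].sum())
    n = d.size

    if n <= exact_limit:
        counts = _null_counts(tuple(sorted(doubled)))
        denom = 2.0**n
        if mid_p:
            p = (counts[w2 + 1 :].sum() + 0.5 * counts[w2]) / denom
        else:
            p = counts[w2:].sum() / denom
        return float(min(max(p, 0.0), 1.0))

    # Normal approximation on the doubled scale.  Each rank enters W2 with
    # probability 1/2 independently, so E[W2] = sum(doubled)/2 and
    # Var(W2) = sum(doubled^2)/4; mid-ranks make the tie correction implicit.
    mean = doubled.sum() / 2.0
    sd = np.sqrt(np.sum(doubled.astype(float) ** 2) / 4.0)
    cc = 0.0 if mid_p else 1.0  # 0.5 on the W+ scale = 1.0 on the doubled scale
    z = (w2 - mean - cc) / sd
    return float(min(max(norm.sf(z), 0.0), 1.0))
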