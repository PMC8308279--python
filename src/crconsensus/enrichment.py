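"""Category over-representation by Fisher's exact test with BH control.

Given a query gene list (e.g. the up-regulated consensus genes of one
condition), a background universe, and a collection of gene categories,
each category is tested with the one-sided hypergeometric tail

    p_raw = P(X >= k),   X ~ Hypergeom(N, K, n)

where N is the universe size, K the category size within the universe, n
the query size and k the observed overlap — the classic over-representation
form of Fisher's exact test.  Raw p-values are adjusted across all tested
categories with the Benjamini–Hochberg step-up procedure; a category is
significant when the adjusted p falls below ``alpha`` (default 1e-4, the
stringent threshold the source analysis used).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["CategoryMap", "EnrichmentResult", "fisher_enrichment"]


@dataclass(frozen=True)
class CategoryMap:
    """One gene category (e.g. a GO Biological Process term)."""

    category_id: str
    category_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"category {self.category_id!r} has no members")


@dataclass(frozen=True)
class EnrichmentResult:
    category_id: str
    category_name: str
    k: int  # query genes in category
    K: int  # category size within the universe
    n: int  # query size
    N: int  # universe size
    p_raw: float
    p_adjusted: float
    significant: bool


def fisher_enrichment(
    query: Iterable[str],
    universe: Iterable[str],
    categories: Sequence[CategoryMap],
    alpha: float = 1e-4,
    *,
    two_sided: bool = False,
) -> list[EnrichmentResult]:
    """Test every category for over-representation of the query in the universe.

    Categories are intersected with the universe before testing; categories
    with no member in the universe are skipped.  Duplicate identifiers
    collapse to sets.  Results are sorted by adjusted p ascending, then
    category id.
    """
    query_set = frozenset(query)
    universe_set = frozenset(universe)
    stray = sorted(query_set - universe_set)
    if stray:
        raise ValueError(f"query genes outside the universe: {stray}")
    N, n = len(universe_set), len(query_set)

    tested: list[tuple[CategoryMap, int, int, float]] = []
    for cat in categories:
        members = cat.members & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & query_set)
        upper = float(hypergeom.sf(k - 1, N, K, n))
        if two_sided:
            # Sum of all outcome probabilities not exceeding the observed one.
            pmf_obs = hypergeom.pmf(k, N, K, n)
            lo, hi = max(0, K + n - N), min(K, n)
            p = float(
                sum(
                    hypergeom.pmf(x, N, K, n)
                    for x in range(lo, hi + 1)
                    if hypergeom.pmf(x, N, K, n) <= pmf_obs * (1 + 1e-12)
                )
            )
        else:
            p = upper
        tested.append((cat, k, K, min(p, 1.0)))

    if not tested:
        return []
    raw = [t[3] for t in tested]
    _, adjusted, _, _ = multipletests(raw, method="fdr_bh")
    results = [
        EnrichmentResult(
            category_id=cat.category_id,
            category_name=cat.category_name,
            k=k,
            K=K,
            n=n,
            N=N,
            p_raw=p,
            p_adjusted=float(p_adj),
            significant=bool(p_adj < alpha),
        )
        for (cat, k, K, p), p_adj in zip(tested, adjusted)
    ]
    results.sort(key=lambda r: (r.p_adjusted, r.category_id))
    return results
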