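"""Direction concordance of study genes against external meta-analysis tables.

External calorie-restriction meta-analyses report, per gene, whether
expression moves up or down across many studies.  Each gene from this
study's consensus lists is scored against every reference column of such a
table: *concordant* if at least one reference reports the gene and every
reporting reference agrees with the study direction; *conflicting* if any
reporting reference disagrees; *not_found* otherwise.  The three labels
partition the study list exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["ConcordanceSummary", "concordance"]

VALID_DIRECTIONS = ("up", "down")
VALID_META_TOKENS = ("up", "down", "absent")


@dataclass(frozen=True)
class ConcordanceSummary:
    concordant: int
    conflicting: int
    not_found: int
    labels: pd.DataFrame  # gene_symbol, study_direction, label

    @property
    def overlapping(self) -> int:
        """Genes found in any reference, regardless of agreement."""
        return self.concordant + self.conflicting


def concordance(
    study_genes: Sequence[tuple[str, str]],
    meta: pd.DataFrame,
) -> ConcordanceSummary:
    """Score (gene, direction) pairs against a gene x reference table.

    ``meta`` is indexed by gene symbol with one column per reference, each
    cell holding 'up', 'down' or 'absent'.  Column order is irrelevant.
    """
    if not meta.empty:
        bad = set(meta.to_numpy().ravel()) - set(VALID_META_TOKENS)
        if bad:
            raise ValueError(f"unknown direction tokens in meta table: {sorted(bad)}")
    rows = []
    for gene, direction in study_genes:
        if direction not in VALID_DIRECTIONS:
            raise ValueError(f"study direction for {gene!r} must be up/down")
        if gene in meta.index:
            reported = [v for v in meta.loc[gene] if v != "absent"]
        else:
            reported = []
        if not reported:
            label = "not_found"
        elif all(v == direction for v in reported):
            label = "concordant"
        else:
            label = "conflicting"
        rows.append({"gene_symbol": gene, "study_direction": direction, "label": label})
    labels = pd.DataFrame(rows, columns=["gene_symbol", "study_direction", "label"])
    counts = labels["label"].value_counts()
    return ConcordanceSummary(
        concordant=int(counts.get("concordant", 0)),
        conflicting=int(counts.get("conflicting", 0)),
        not_found=int(counts.get("not_found", 0)),
        labels=labels,
    )
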