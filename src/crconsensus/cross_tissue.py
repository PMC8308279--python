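"""Cross-tissue commonality counting and within-tissue top ranking.

Two complementary summaries of the direction matrix:

* *commonality*: for each probe set, count in how many of the 36 CR
  conditions it shows the same informative direction; probes whose
  informative entries mix up and down are not single-direction candidates
  and are dropped.  Ranking by this count surfaces genes regulated across
  multiple organs.
* *top ranking*: within one tissue, order the CR-responsive probe sets by
  their signal log ratio in the strongest intervention (one month of 30%
  restriction), descending for up-regulated lists and ascending for
  down-regulated lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .consensus import DirectionMatrix
from .design import ConditionKey, condition_columns

__all__ = ["CommonalityRecord", "overlap_count", "top_common", "rank_top"]

N_CONDITIONS = 36

#: Sort-key condition: the most robust intervention in the study design.
RANK_CONDITION = ("1m", 30)


@dataclass(frozen=True)
class CommonalityRecord:
    probe_set_id: str
    gene_symbol: str
    direction: str  # up | down
    n_conditions: int

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")
        if not 0 <= self.n_conditions <= N_CONDITIONS:
            raise ValueError("n_conditions outside 0..36")


def overlap_count(
    row: Mapping[str, str] | pd.Series,
    *,
    probe_set_id: str = "",
    gene_symbol: str = "",
) -> CommonalityRecord | None:
    """Single-direction commonality of one probe's row over the 36 conditions.

    ``row`` maps condition column labels to 'up'/'down'/'none'; conditions
    missing from the mapping count as 'none'.  Returns ``None`` when the
    row mixes both directions or is entirely non-informative.
    """
    labels = set(condition_columns())
    extra = [k for k in row.keys() if k not in labels]
    if extra:
        raise ValueError(f"entries outside the 36-condition design: {extra}")
    values = [v for v in row.values() if v != "none"]
    bad = [v for v in values if v not in ("up", "down")]
    if bad:
        raise ValueError(f"invalid direction entries: {sorted(set(bad))}")
    dirs = set(values)
    if len(dirs) != 1:
        return None  # mixed directions, or informative nowhere
    return CommonalityRecord(
        probe_set_id=probe_set_id,
        gene_symbol=gene_symbol,
        direction=dirs.pop(),
        n_conditions=len(values),
    )


def top_common(
    matrix: DirectionMatrix,
    min_conditions: int,
    *,
    symbols: Mapping[str, str] | None = None,
    direction: str | None = None,
) -> list[CommonalityRecord]:
    """Probes consistent in at least ``min_conditions`` of the 36 conditions.

    Sorted by count descending, ties broken by probe_set_id ascending.
    ``symbols`` optionally maps probe set ids to gene symbols (unmapped
    probes keep an empty symbol); ``direction`` restricts to 'up' or 'down'.
    """
    if not 1 <= min_conditions <= N_CONDITIONS:
        raise ValueError("min_conditions must be in 1..36")
    symbols = symbols or {}
    records = []
    for probe in matrix.frame.index:
        rec = overlap_count(
            matrix.frame.loc[probe].to_dict(),
            probe_set_id=probe,
            gene_symbol=symbols.get(probe, ""),
        )
        if rec is None or rec.n_conditions < min_conditions:
            continue
        if direction is not None and rec.direction != direction:
            continue
        records.append(rec)
    return sorted(records, key=lambda r: (-r.n_conditions, r.probe_set_id))


def rank_top(
    responsive: Iterable[str],
    slr: pd.DataFrame,
    tissue: str,
    direction: str,
    n: int,
) -> list[tuple[str, float]]:
    """Top-``n`` responsive probes by SLR at the (1m, 30%) sort-key condition.

    ``slr`` is a probe x condition table of signal log ratios with condition
    column labels.  Up lists sort descending (largest induction first), down
    lists ascending (strongest repression first); ties break by probe id.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    key = ConditionKey(tissue, *RANK_CONDITION).column
    if key not in slr.columns:
        raise ValueError(f"SLR table lacks sort-key condition {key!r}")
    pairs = []
    for probe in sorted(responsive):
        if probe not in slr.index or pd.isna(slr.at[probe, key]):
            raise ValueError(f"probe {probe!r} has no SLR at {key!r}")
        pairs.append((probe, float(slr.at[probe, key])))
    sign = -1.0 if direction == "up" else 1.0
    pairs.sort(key=lambda pv: (sign * pv[1], pv[0]))
    return pairs[:n]
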