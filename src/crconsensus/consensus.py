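"""Informative-probe filtering and the dose-consistent "CR responsive" consensus.

A probe set is *informative* in one CR condition when the comparison against
its control passes a conservative filter: neither chip of the hybridization
pair may be called absent, and the change call must be a firm increase or
decrease (no-change and the two marginal change calls are eliminated).  For
the tissue hybridized in duplicate (adipose), both chip pairs must
independently give the same firm direction.

A probe set is *CR responsive* in a tissue when its informative direction is
identical in every condition of that tissue — all four restriction levels
and, by default, both durations.  This intersection-across-doses filter is
the study's substitute for replicate-based statistics in a pooled-RNA
design: consistency across independent dose conditions stands in for
consistency across biological replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .call_engine import (
    CHANGE_FROM_CODE,
    DETECTION_FROM_CODE,
    ChangeResult,
    DetectionResult,
)
from .design import (
    ConditionKey,
    condition_columns,
    design_conditions,
    n_replicates,
    tissue_conditions,
    tissue_durations,
)

__all__ = [
    "CallRecord",
    "DirectionMatrix",
    "informative_direction",
    "build_direction_matrix",
    "direction_matrix_from_calls",
    "count_informative",
    "cr_responsive",
    "informative_counts_table",
]

DIRECTION_TOKENS = {"up": "U", "down": "D", "none": "."}
DIRECTION_FROM_TOKEN = {v: k for k, v in DIRECTION_TOKENS.items()}


@dataclass(frozen=True)
class CallRecord:
    """Calls for one probe set in one condition on one chip pair."""

    probe_set_id: str
    condition: ConditionKey
    replicate_index: int
    baseline_detection: DetectionResult
    experiment_detection: DetectionResult
    change: ChangeResult

    def __post_init__(self) -> None:
        if not 0 <= self.replicate_index <= 1:
            raise ValueError("replicate_index must be 0 or 1")
        if self.replicate_index == 1 and n_replicates(self.condition.tissue) == 1:
            raise ValueError(
                f"tissue {self.condition.tissue!r} is not hybridized in duplicate"
            )


@dataclass
class DirectionMatrix:
    """Probe x condition matrix of informative directions ('up'/'down'/'none')."""

    frame: pd.DataFrame  # index: probe_set_id; columns: condition labels

    def __post_init__(self) -> None:
        known = set(condition_columns())
        bad = [c for c in self.frame.columns if c not in known]
        if bad:
            raise ValueError(f"unknown condition columns {bad}")
        values = self.frame.to_numpy()
        if values.size and not np.isin(values, list(DIRECTION_TOKENS)).all():
            raise ValueError("entries must be 'up', 'down' or 'none'")

    @property
    def probes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def conditions(self) -> list[ConditionKey]:
        return [ConditionKey.from_column(c) for c in self.frame.columns]

    def row(self, probe_set_id: str) -> pd.Series:
        return self.frame.loc[probe_set_id]


def _single_record_direction(
    baseline_call: str, experiment_call: str, change_call: str
) -> str:
    """Direction of one chip pair: 'up', 'down' or 'none'.

    Absent on either chip excludes the pair; only firm increase/decrease
    change calls count (marginal detection calls are *not* excluded).
    """
    if baseline_call == "absent" or experiment_call == "absent":
        return "none"
    if change_call == "increase":
        return "up"
    if change_call == "decrease":
        return "down"
    return "none"


def informative_direction(records: Sequence[CallRecord]) -> str:
    """Consensus informative direction for one probe set in one condition.

    Non-duplicated tissues contribute exactly one record; adipose
    contributes two, and is informative only when both chip pairs give the
    same firm direction.
    """
    if not records:
        raise ValueError("no call records supplied")
    first = records[0]
    expected = n_replicates(first.condition.tissue)
    if len(records) != expected:
        raise ValueError(
            f"{first.condition.tissue} condition needs {expected} record(s), "
            f"got {len(records)}"
        )
    if len({(r.probe_set_id, r.condition) for r in records}) != 1:
        raise ValueError("records mix probe sets or conditions")
    if len({r.replicate_index for r in records}) != len(records):
        raise ValueError("duplicate replicate_index in records")
    directions = [
        _single_record_direction(
            r.baseline_detection.call, r.experiment_detection.call, r.change.call
        )
        for r in records
    ]
    if len(directions) == 1:
        return directions[0]
    if directions[0] == directions[1] and directions[0] != "none":
        return directions[0]
    return "none"


def build_direction_matrix(records: Iterable[CallRecord]) -> DirectionMatrix:
    """Assemble the probe x condition direction matrix from call records.

    Probes with no informative entry anywhere are retained as all-'none'
    rows.  Conditions never seen in the records simply do not appear as
    columns.
    """
    records = list(records)
    seen: set[tuple[str, ConditionKey, int]] = set()
    grouped: dict[tuple[str, ConditionKey], list[CallRecord]] = {}
    for rec in records:
        key3 = (rec.probe_set_id, rec.condition, rec.replicate_index)
        if key3 in seen:
            raise ValueError(f"duplicate record for {key3}")
        seen.add(key3)
        grouped.setdefault((rec.probe_set_id, rec.condition), []).append(rec)

    probes = sorted({r.probe_set_id for r in records})
    conditions = [c for c in design_conditions() if any(k[1] == c for k in grouped)]
    frame = pd.DataFrame(
        "none", index=probes, columns=[c.column for c in conditions], dtype=object
    )
    for (probe, cond), recs in grouped.items():
        frame.at[probe, cond.column] = informative_direction(recs)
    return DirectionMatrix(frame)


def direction_matrix_from_calls(calls: pd.DataFrame) -> DirectionMatrix:
    """Vectorized path from a call table (``compute_call_table`` output).

    Applies the same filter as :func:`informative_direction` to every row,
    then reconciles duplicate chips within each (probe, condition).
    """
    required = {
        "probe_set_id",
        "tissue",
        "duration",
        "cr_level",
        "replicate_index",
        "detection_call_baseline",
        "detection_call_experiment",
        "change_call",
    }
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"call table missing columns {sorted(missing)}")
    df = calls.copy()
    det_base = df["detection_call_baseline"].map(DETECTION_FROM_CODE)
    det_exp = df["detection_call_experiment"].map(DETECTION_FROM_CODE)
    change = df["change_call"].map(CHANGE_FROM_CODE)
    if det_base.isna().any() or det_exp.isna().any() or change.isna().any():
        raise ValueError("unknown call code in call table")
    direction = np.where(
        (det_base != "absent") & (det_exp != "absent") & (change == "increase"),
        "up",
        np.where(
            (det_base != "absent") & (det_exp != "absent") & (change == "decrease"),
            "down",
            "none",
        ),
    )
    df["_direction"] = direction
    df["_column"] = (
        df["tissue"] + "_" + df["duration"] + "_" + df["cr_level"].astype(int).astype(str)
    )
    dup = df.duplicated(["probe_set_id", "_column", "replicate_index"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"duplicate call rows for {first['probe_set_id']} in {first['_column']}"
        )

    def combine(group: pd.Series) -> str:
        vals = group.to_numpy()
        if vals.size == 1:
            return vals[0]
        if (vals[0] == vals[1]) and vals[0] != "none":
            return vals[0]
        return "none"

    agg = (
        df.groupby(["probe_set_id", "_column"], sort=False)["_direction"]
        .agg(combine)
        .unstack(fill_value="none")
    )
    ordered = [c for c in condition_columns() if c in agg.columns]
    agg = agg.reindex(columns=ordered, fill_value="none").sort_index()
    agg.columns.name = None
    agg.index.name = None
    return DirectionMatrix(agg)


def count_informative(matrix: DirectionMatrix, condition: ConditionKey) -> int:
    """Number of probes with an informative direction in one condition."""
    if condition.column not in matrix.frame.columns:
        raise ValueError(f"condition {condition.column!r} not in matrix")
    col = matrix.frame[condition.column]
    return int((col != "none").sum())


def cr_responsive(
    matrix: DirectionMatrix,
    tissue: str,
    *,
    duration: str | None = None,
) -> tuple[set[str], set[str]]:
    """Up- and down-responsive probe sets for one tissue.

    A probe is up-responsive iff its entry is 'up' in every condition of the
    tissue (all CR levels, both durations where the tissue has both);
    symmetric for down.  Passing ``duration`` restricts the intersection to
    one duration's four levels.
    """
    if duration is None:
        conds = tissue_conditions(tissue)
    else:
        if duration not in tissue_durations(tissue):
            raise ValueError(f"tissue {tissue!r} has no duration {duration!r}")
        conds = tuple(c for c in tissue_conditions(tissue) if c.duration == duration)
    cols = [c.column for c in conds]
    missing = [c for c in cols if c not in matrix.frame.columns]
    if missing:
        raise ValueError(f"matrix lacks conditions {missing} for tissue {tissue!r}")
    sub = matrix.frame[cols]
    up = set(sub.index[(sub == "up").all(axis=1)])
    down = set(sub.index[(sub == "down").all(axis=1)])
    return up, down


def informative_counts_table(matrix: DirectionMatrix) -> pd.DataFrame:
    """Per-condition informative counts plus the per-tissue consensus count.

    One row per tissue x duration with columns for the four CR levels, and
    an ``overlap`` column giving |up-responsive| + |down-responsive| for the
    tissue (shared across its durations).
    """
    rows = []
    for cond in design_conditions():
        if cond.column not in matrix.frame.columns:
            continue
        rows.append(
            {
                "tissue": cond.tissue,
                "duration": cond.duration,
                "cr_level": cond.cr_level,
                "n_informative": count_informative(matrix, cond),
            }
        )
    long = pd.DataFrame(rows)
    table = long.pivot_table(
        index=["tissue", "duration"],
        columns="cr_level",
        values="n_informative",
        sort=False,
    ).reset_index()
    table.columns.name = None
    overlaps = {}
    for tissue in table["tissue"].unique():
        up, down = cr_responsive(matrix, tissue)
        overlaps[tissue] = len(up) + len(down)
    table["overlap"] = table["tissue"].map(overlaps)
    return table
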