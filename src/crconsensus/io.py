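"""Readers and writers for the pipeline's tabular formats.

All tables are UTF-8 TSV with a header row; '.' is the null token.  Lines
starting with '#' are comments.  Schema violations raise
:class:`SchemaError` naming file, line and column.  Packaged fixtures
transcribing the study's published summary tables (top-ranked log ratios,
cross-tissue commonality entries, meta-analysis directions) are exposed via
the ``load_*_fixture`` helpers.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .consensus import DIRECTION_FROM_TOKEN, DIRECTION_TOKENS, DirectionMatrix
from .design import (
    CONTROL_LEVEL,
    CR_LEVELS,
    TISSUES,
    condition_columns,
    n_replicates,
    tissue_durations,
)
from .enrichment import CategoryMap

__all__ = [
    "SchemaError",
    "read_design",
    "read_intensities",
    "read_calls",
    "write_calls",
    "read_direction_matrix",
    "write_direction_matrix",
    "read_slr_table",
    "read_gmt",
    "read_gene_list",
    "read_meta_table",
    "load_top_ranked_fixture",
    "load_commonality_fixture",
    "load_meta_fixture",
    "commonality_fixture_matrix",
    "study_gene_directions",
    "fixture_slr_table",
]

NULL = "."


class SchemaError(ValueError):
    """A tabular input violated its schema."""

    def __init__(self, path, message, line=None, column=None):
        loc = str(path)
        if line is not None:
            loc += f", line {line}"
        if column is not None:
            loc += f", column {column!r}"
        super().__init__(f"{loc}: {message}")


def _read_tsv(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise SchemaError(path, f"cannot parse TSV: {exc}") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(path, f"missing columns {sorted(missing)}")
    return df


def read_design(path: str | Path) -> pd.DataFrame:
    """Design table: chip_id, tissue, duration, cr_level, role, replicate_index."""
    df = _read_tsv(
        path, ["chip_id", "tissue", "duration", "cr_level", "role", "replicate_index"]
    )
    valid_levels = {str(lvl) for lvl in (CONTROL_LEVEL,) + CR_LEVELS}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1 (comments aside)
        if row["tissue"] not in TISSUES:
            raise SchemaError(path, f"unknown tissue {row['tissue']!r}", line, "tissue")
        if row["duration"] not in tissue_durations(row["tissue"]):
            raise SchemaError(
                path,
                f"tissue {row['tissue']!r} has no duration {row['duration']!r}",
                line,
                "duration",
            )
        if row["cr_level"] not in valid_levels:
            raise SchemaError(
                path, f"unknown cr_level {row['cr_level']!r}", line, "cr_level"
            )
        if row["role"] not in ("control", "cr"):
            raise SchemaError(path, f"unknown role {row['role']!r}", line, "role")
        if (row["role"] == "control") != (int(row["cr_level"]) == CONTROL_LEVEL):
            raise SchemaError(path, "role inconsistent with cr_level", line, "role")
        rep = int(row["replicate_index"])
        if not 0 <= rep < n_replicates(row["tissue"]):
            raise SchemaError(
                path,
                f"replicate_index {rep} invalid for {row['tissue']!r}",
                line,
                "replicate_index",
            )
    if df["chip_id"].duplicated().any():
        dup = df["chip_id"][df["chip_id"].duplicated()].iloc[0]
        raise SchemaError(path, f"duplicate chip_id {dup!r}", column="chip_id")
    df["cr_level"] = df["cr_level"].astype(int)
    df["replicate_index"] = df["replicate_index"].astype(int)
    return df


def read_intensities(path: str | Path) -> pd.DataFrame:
    """Probe intensity table(s); ``path`` may be one TSV or a directory of them."""
    p = Path(path)
    if p.is_dir():
        files = sorted(p.glob("chip_*.tsv")) or sorted(p.glob("*.tsv"))
        if not files:
            raise SchemaError(p, "no intensity TSVs found")
        frames = [read_intensities(f) for f in files]
        return pd.concat(frames, ignore_index=True)
    df = _read_tsv(p, ["chip_id", "probe_set_id", "probe_index", "pm", "mm"])
    try:
        df["probe_index"] = df["probe_index"].astype(int)
        df["pm"] = df["pm"].astype(float)
        df["mm"] = df["mm"].astype(float)
    except ValueError as exc:
        raise SchemaError(p, f"non-numeric intensity field: {exc}") from exc
    if (df["pm"] <= 0).any() or (df["mm"] <= 0).any():
        bad = df.index[(df["pm"] <= 0) | (df["mm"] <= 0)][0]
        raise SchemaError(p, "non-positive intensity", line=int(bad) + 2)
    if df.duplicated(["chip_id", "probe_set_id", "probe_index"]).any():
        raise SchemaError(p, "duplicate (chip_id, probe_set_id, probe_index) row")
    return df


CALL_COLUMNS = [
    "probe_set_id",
    "tissue",
    "duration",
    "cr_level",
    "replicate_index",
    "detection_p_baseline",
    "detection_call_baseline",
    "detection_p_experiment",
    "detection_call_experiment",
    "change_p",
    "change_call",
    "slr",
]


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False, na_rep=NULL)


def read_calls(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, CALL_COLUMNS)
    df["cr_level"] = df["cr_level"].astype(int)
    df["replicate_index"] = df["replicate_index"].astype(int)
    for col in ("detection_p_baseline", "detection_p_experiment", "change_p", "slr"):
        df[col] = df[col].astype(float)
    return df


def write_direction_matrix(matrix: DirectionMatrix, path: str | Path) -> None:
    """Probe x condition TSV with U/D/. entries."""
    frame = matrix.frame.replace(DIRECTION_TOKENS)
    frame.index.name = "probe_set_id"
    frame.to_csv(path, sep="\t")


def read_direction_matrix(path: str | Path) -> DirectionMatrix:
    df = _read_tsv(path, ["probe_set_id"])
    df = df.set_index("probe_set_id")
    known = set(condition_columns())
    for col in df.columns:
        if col not in known:
            raise SchemaError(path, f"unknown condition column {col!r}", column=col)
        bad = set(df[col]) - set(DIRECTION_FROM_TOKEN)
        if bad:
            raise SchemaError(
                path, f"invalid direction tokens {sorted(bad)}", column=col
            )
    return DirectionMatrix(df.replace(DIRECTION_FROM_TOKEN))


def read_slr_table(path: str | Path) -> pd.DataFrame:
    """Probe x condition table of signal log ratios ('.' = missing)."""
    df = _read_tsv(path, ["probe_set_id"]).set_index("probe_set_id")
    known = set(condition_columns())
    for col in df.columns:
        if col not in known:
            raise SchemaError(path, f"unknown condition column {col!r}", column=col)
    return df.replace(NULL, np.nan).astype(float)


def read_gmt(path: str | Path) -> list[CategoryMap]:
    """Standard GMT: category_id TAB description TAB member genes..."""
    categories = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    path, "GMT line needs id, description and >=1 member", lineno
                )
            cat_id, name, *members = fields
            members = [m for m in members if m]
            if not members:
                raise SchemaError(path, f"category {cat_id!r} has no members", lineno)
            if cat_id in seen:
                raise SchemaError(path, f"duplicate category {cat_id!r}", lineno)
            seen.add(cat_id)
            categories.append(CategoryMap(cat_id, name, frozenset(members)))
    return categories


def read_gene_list(path: str | Path) -> list[str]:
    """Newline-delimited gene identifiers; blanks and '#' comments skipped."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            token = raw.strip()
            if token and not token.startswith("#"):
                out.append(token)
    return out


def read_meta_table(path: str | Path) -> pd.DataFrame:
    """Meta-analysis direction table: gene_symbol + >=1 reference columns."""
    df = _read_tsv(path, ["gene_symbol"]).set_index("gene_symbol")
    ref_cols = [c for c in df.columns if c.startswith("ref")]
    if not ref_cols:
        raise SchemaError(path, "need at least one reference column (ref1, ref2, ...)")
    meta = df[ref_cols]
    bad = set(meta.to_numpy().ravel()) - {"up", "down", "absent"}
    if bad:
        raise SchemaError(path, f"unknown direction tokens {sorted(bad)}")
    return meta


# ---------------------------------------------------------------------------
# Packaged fixtures (transcriptions of the study's published summary tables)


def _fixture_path(name: str):
    return importlib.resources.files("crconsensus.data") / name


def load_top_ranked_fixture(direction: str) -> pd.DataFrame:
    """Published top-five ranked log ratios per tissue ('up' or 'down')."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    with importlib.resources.as_file(_fixture_path(f"top_ranked_{direction}.tsv")) as p:
        return _read_tsv(p, ["tissue", "probe_set_id", "gene_symbol"])


def fixture_slr_table(ranked: pd.DataFrame, tissue: str) -> pd.DataFrame:
    """Reshape one tissue's ranked-fixture rows into a probe x condition table."""
    sub = ranked[ranked["tissue"] == tissue].set_index("probe_set_id")
    out = {}
    for duration in tissue_durations(tissue):
        for level in CR_LEVELS:
            col = f"slr_{duration}_{level}"
            out[f"{tissue}_{duration}_{level}"] = (
                sub[col].replace(NULL, np.nan).astype(float)
            )
    return pd.DataFrame(out)


def load_commonality_fixture() -> pd.DataFrame:
    """Published cross-tissue commonality entries for the 20 top probes."""
    with importlib.resources.as_file(_fixture_path("commonality.tsv")) as p:
        df = _read_tsv(p, ["probe_set_id", "gene_symbol", "direction", "reported_count"])
    df["reported_count"] = df["reported_count"].astype(int)
    return df


def commonality_fixture_matrix() -> DirectionMatrix:
    """The commonality fixture as a DirectionMatrix over all 36 conditions."""
    df = load_commonality_fixture().set_index("probe_set_id")
    entries = df[condition_columns()].replace(DIRECTION_FROM_TOKEN)
    return DirectionMatrix(entries)


def study_gene_directions() -> list[tuple[str, str]]:
    """(gene_symbol, direction) for the named genes of the commonality fixture.

    Probes without a symbol are dropped and duplicate probes per gene
    collapse to one entry, yielding the study's 18 most commonly regulated
    genes across tissues.
    """
    df = load_commonality_fixture()
    seen: dict[str, str] = {}
    for row in df.itertuples():
        if row.gene_symbol and row.gene_symbol not in seen:
            seen[row.gene_symbol] = row.direction
    return list(seen.items())


def load_meta_fixture() -> pd.DataFrame:
    """Published meta-analysis direction table, indexed by gene symbol."""
    with importlib.resources.as_file(_fixture_path("meta_directions.tsv")) as p:
        df = _read_tsv(p, ["gene_symbol", "study_direction", "ref1", "ref2"])
    return df.set_index("gene_symbol")[["ref1", "ref2"]]
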