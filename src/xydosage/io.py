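"""Readers and writers for the package's plain-text formats.

Count matrices are gene x sample TSVs (header row of sample ids, first
column gene ids); sample sheets, gene annotations, allelic-study tables and
depth tables are column-typed TSVs; peaks are BED3+; gene-set collections
are GMT. All coordinates are 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_annotation",
    "read_bed",
    "read_gmt",
    "read_depth_table",
    "read_study_table",
]

SAMPLE_SHEET_COLUMNS = ["cell_type", "x_copies", "y_copies", "chr21_copies", "batch", "condition"]


def read_count_matrix(path) -> pd.DataFrame:
    """Read a gene x sample TSV of non-negative integer counts.

    Rejects duplicate gene or sample ids and pinpoints non-integer or
    negative cells by row and column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[[not np.issubdtype(df[c].dtype, np.number) for c in df.columns]][0]
        row = df.index[~df[bad].apply(lambda v: isinstance(v, (int, np.integer)))][0]
        raise ValueError(f"non-integer count at gene {row!r}, sample {bad!r} in {path}")
    if np.any(arr != np.floor(arr)):
        g, s = np.argwhere(arr != np.floor(arr))[0]
        raise ValueError(f"non-integer count at gene {df.index[g]!r}, sample {df.columns[s]!r}")
    if np.any(arr < 0):
        g, s = np.argwhere(arr < 0)[0]
        raise ValueError(f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}")
    df.index.name = "gene_id"
    return df.astype(np.int64)


def write_count_matrix(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet TSV indexed by sample_id."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} missing columns {missing}")
    if df.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    if (df["x_copies"] < 0).any() or (df["y_copies"] < 0).any():
        raise ValueError("copy numbers must be non-negative")
    return df


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.rename_axis("sample_id").to_csv(path, sep="\t")


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene annotation TSV: gene_id, chromosome, start, end, strand,
    effective_length, biotype (0-based half-open intervals)."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    for col in ("chromosome", "start", "end", "strand", "effective_length"):
        if col not in df.columns:
            raise ValueError(f"annotation {path} missing column {col!r}")
    if (df["effective_length"] <= 0).any():
        raise ValueError("effective_length must be positive")
    if (df["start"] >= df["end"]).any():
        raise ValueError("invalid gene intervals (start >= end)")
    return df


def read_bed(path) -> pd.DataFrame:
    """BED3+ peak intervals (chrom, start, end[, name, score])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"invalid BED intervals in {path}")
    return df


def read_gmt(path) -> dict[str, set]:
    """GMT gene-set collection: set name, description, then members."""
    out: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line in {path}: {line[:60]!r}")
        out[fields[0]] = {m for m in fields[2:] if m}
    return out


def read_depth_table(path) -> pd.DataFrame:
    """Per-sample binned depth TSV: sample_id, bin_id, region, gc_fraction, depth."""
    df = pd.read_csv(path, sep="\t")
    needed = {"sample_id", "bin_id", "region", "gc_fraction", "depth"}
    if not needed <= set(df.columns):
        raise ValueError(f"depth table {path} missing columns {sorted(needed - set(df.columns))}")
    if (df["depth"] < 0).any():
        raise ValueError("depths must be non-negative")
    return df


def read_study_table(path) -> pd.DataFrame:
    """An allelic-study table in whichever dialect its columns declare."""
    return pd.read_csv(path, sep="\t")
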