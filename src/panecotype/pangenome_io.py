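"""Readers and writers for the three tabular formats the pipeline touches.

* Rtab: tab-separated gene presence/absence (rows = gene clusters, first
  column the cluster id, remaining columns genome ids, cells counts that are
  binarized on read) — the matrix dialect emitted by Roary/PanTA-style
  pangenome builders.
* Metadata: CSV with the documented header (see ``types.METADATA_COLUMNS``).
* FastANI: headerless tab-separated ``query  reference  ANI  mapped  total``.

All readers accept gzip-compressed input (by file extension); every
write -> read round-trip is the identity.
"""

from __future__ import annotations

import logging
import os
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    ANITable,
    Dataset,
    GeneClusterMatrix,
    METADATA_COLUMNS,
    ValidationError,
    validate_metadata_frame,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_rtab", "write_rtab",
    "read_metadata", "write_metadata",
    "read_fastani", "write_fastani",
    "Dataset",
]


class ParseError(ValueError):
    """A file could not be parsed; the message carries location context."""


# ---------------------------------------------------------------------------
# Rtab
# ---------------------------------------------------------------------------

def _read_header_line(path) -> str:
    import gzip as _gzip
    opener = _gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return fh.readline().rstrip("\n")


def read_rtab(path) -> GeneClusterMatrix:
    """Read an Rtab presence/absence matrix; counts >1 are binarized to 1."""
    header = _read_header_line(path).split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({g for g in header if header.count(g) > 1})
        raise ParseError(f"{path}: duplicate genome ids in header: {dupes}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed Rtab ({exc})") from exc
    genome_ids = [str(c) for c in df.columns]
    cluster_ids = [str(c) for c in df.index]
    if len(set(cluster_ids)) != len(cluster_ids):
        dupes = df.index[df.index.duplicated()].tolist()
        raise ParseError(f"{path}: duplicate cluster ids: {dupes[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        # locate first offending cell for the error message
        for i, row in enumerate(df.itertuples(index=False), start=2):
            for cell in row:
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(f"{path}: non-numeric cell {cell!r} at line {i}") from exc
        raise ParseError(f"{path}: non-numeric data ({exc})") from exc
    if np.isnan(values).any():
        i = int(np.argwhere(np.isnan(values))[0][0]) + 2
        raise ParseError(f"{path}: missing cell at line {i}")
    if (values < 0).any():
        raise ParseError(f"{path}: negative gene counts")
    presence = (values > 0).astype(np.uint8).T  # genomes x clusters
    return GeneClusterMatrix(genome_ids, cluster_ids, presence)


def write_rtab(matrix: GeneClusterMatrix, path) -> None:
    df = pd.DataFrame(matrix.presence.T, index=matrix.cluster_ids, columns=matrix.genome_ids)
    df.index.name = "Gene"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Read the per-genome metadata CSV.

    Rows without an ecotype label are kept but flagged (``has_ecotype`` is
    False) so supervised stages can exclude them; missing depth is allowed.
    Unknown extra columns are preserved.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("genome_id", "ecotype", "completeness_pct") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: metadata missing required columns {missing}")
    for c in METADATA_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    for c in ("depth_m", "completeness_pct", "genome_size_bp", "gc_pct",
              "coding_density", "hypothetical_fraction"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    validate_metadata_frame(df)
    df["has_ecotype"] = df["ecotype"].notna()
    n_eco = int(df["has_ecotype"].sum())
    n_depth = int((df["has_ecotype"] & df["depth_m"].notna()).sum())
    logger.info("metadata: %d rows, %d with ecotype, %d of those with depth",
                len(df), n_eco, n_depth)
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    cols = METADATA_COLUMNS + [c for c in metadata.columns if c not in METADATA_COLUMNS]
    metadata[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# FastANI
# ---------------------------------------------------------------------------

def _normalize_genome_id(name: str) -> str:
    """Strip directory and sequence-file extensions from a FastANI path column."""
    base = os.path.basename(str(name))
    for ext in (".gz", ".fasta", ".fna", ".fa"):
        if base.endswith(ext):
            base = base[: -len(ext)]
    return base


def read_fastani(path) -> ANITable:
    """Read FastANI tabular output (>=3 tab-separated columns, no header).

    Real FastANI files simply lack rows for pairs below the reporting floor,
    so every present row is kept as given; pairs absent from the file are
    missing.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None)
    except pd.errors.EmptyDataError:
        return ANITable()
    if df.shape[1] < 3:
        raise ParseError(f"{path}: FastANI output needs >=3 columns, got {df.shape[1]}")
    df = df.iloc[:, :5]
    df.columns = ANITable.COLUMNS[: df.shape[1]]
    for c in ("mapped", "total"):
        if c not in df.columns:
            df[c] = np.nan
    df["query"] = df["query"].map(_normalize_genome_id)
    df["reference"] = df["reference"].map(_normalize_genome_id)
    ani = pd.to_numeric(df["ani_pct"], errors="coerce")
    if ani.isna().any():
        i = int(ani.index[ani.isna()][0]) + 1
        raise ParseError(f"{path}: non-numeric ANI value at line {i}")
    if ((ani < 0) | (ani > 100)).any():
        bad = float(ani[(ani < 0) | (ani > 100)].iloc[0])
        raise ValidationError(f"{path}: ANI value {bad} outside [0, 100]")
    df["ani_pct"] = ani
    return ANITable(df[ANITable.COLUMNS])


def write_fastani(ani: ANITable, path) -> None:
    """Write FastANI-style rows; censored (missing-ANI) pairs are omitted,
    matching how the real tool reports."""
    rep = ani.reported().copy()
    rep["mapped"] = rep["mapped"].fillna(0).astype(int)
    rep["total"] = rep["total"].fillna(0).astype(int)
    rep.to_csv(path, sep="\t", header=False, index=False,
               columns=ANITable.COLUMNS, float_format="%.4f")
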