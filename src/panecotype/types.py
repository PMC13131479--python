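"""Core in-memory containers shared across the pipeline.

The pipeline moves three objects around: a binary genomes x gene-cluster
presence/absence matrix, a per-genome metadata table, and a pairwise
average-nucleotide-identity (ANI) table.  The matrix is a thin wrapper around
a dense ``uint8`` array with ordered id lists; metadata and ANI travel as
:class:`pandas.DataFrame` objects with documented columns, with a row-level
:class:`GenomeMetadata` dataclass for callers who prefer records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "GeneClusterMatrix",
    "GenomeMetadata",
    "ANITable",
    "Dataset",
    "METADATA_COLUMNS",
    "metadata_to_frame",
    "frame_to_metadata",
    "validate_metadata_frame",
]

#: Documented metadata header, in on-disk column order.
METADATA_COLUMNS = [
    "genome_id",
    "ecotype",
    "clade",
    "depth_m",
    "completeness_pct",
    "batch",
    "genome_size_bp",
    "gc_pct",
    "coding_density",
    "hypothetical_fraction",
]

ECOTYPES = ("HL", "LL")


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass
class GeneClusterMatrix:
    """Binary genomes x gene-clusters presence/absence matrix.

    ``presence[i, j] == 1`` iff genome ``genome_ids[i]`` carries a member of
    gene cluster ``cluster_ids[j]``.
    """

    genome_ids: list
    cluster_ids: list
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.genome_ids = list(self.genome_ids)
        self.cluster_ids = list(self.cluster_ids)
        self.presence = np.asarray(self.presence)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.presence.ndim != 2:
            raise ValidationError("presence must be a 2-D array")
        n, p = self.presence.shape
        if n != len(self.genome_ids) or p != len(self.cluster_ids):
            raise ValidationError(
                f"dimension mismatch: presence is {n}x{p} but there are "
                f"{len(self.genome_ids)} genome ids and {len(self.cluster_ids)} cluster ids"
            )
        if len(set(self.genome_ids)) != n:
            raise ValidationError("duplicate genome ids")
        if len(set(self.cluster_ids)) != p:
            raise ValidationError("duplicate cluster ids")
        vals = np.unique(self.presence)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("presence entries must be 0/1")

    # -- convenience ------------------------------------------------------
    @property
    def n_genomes(self) -> int:
        return self.presence.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.presence.shape[1]

    def genome_index(self, ids: Iterable) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genome_ids)}
        try:
            return np.array([lookup[g] for g in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown genome id {exc.args[0]!r}") from None

    def cluster_index(self, ids: Iterable) -> np.ndarray:
        lookup = {c: j for j, c in enumerate(self.cluster_ids)}
        return np.array([lookup[c] for c in ids], dtype=int)

    def subset_genomes(self, ids: Sequence) -> "GeneClusterMatrix":
        idx = self.genome_index(ids)
        return GeneClusterMatrix(list(ids), self.cluster_ids, self.presence[idx])

    def subset_clusters(self, ids: Sequence) -> "GeneClusterMatrix":
        idx = self.cluster_index(ids)
        return GeneClusterMatrix(self.genome_ids, list(ids), self.presence[:, idx])

    def prevalence(self, genome_mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Per-cluster fraction of (selected) genomes carrying the cluster."""
        if genome_mask is None:
            return self.presence.mean(axis=0)
        genome_mask = np.asarray(genome_mask, dtype=bool)
        if genome_mask.sum() == 0:
            raise ValidationError("prevalence over an empty genome selection")
        return self.presence[genome_mask].mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence, index=self.genome_ids, columns=self.cluster_ids)


@dataclass
class GenomeMetadata:
    """One genome's metadata record.

    ``depth_m`` is the depth of isolation in meters (``None`` when unknown);
    ``completeness_pct`` is a BUSCO-style completeness score in (0, 100].
    """

    genome_id: str
    ecotype: Optional[str] = None  # "HL" / "LL"; None when unlabeled
    clade: Optional[str] = None
    depth_m: Optional[float] = None
    completeness_pct: float = 100.0
    batch: Optional[str] = None
    genome_size_bp: Optional[float] = None
    gc_pct: Optional[float] = None
    coding_density: Optional[float] = None
    hypothetical_fraction: Optional[float] = None

    def validate(self) -> None:
        if self.ecotype is not None and self.ecotype not in ECOTYPES:
            raise ValidationError(f"{self.genome_id}: ecotype must be HL or LL, got {self.ecotype!r}")
        if self.clade is not None and self.ecotype is not None:
            if not str(self.clade).startswith(self.ecotype):
                raise ValidationError(
                    f"{self.genome_id}: clade {self.clade!r} does not match ecotype {self.ecotype!r}"
                )
        if not (0 < self.completeness_pct <= 100):
            raise ValidationError(
                f"{self.genome_id}: completeness_pct must be in (0, 100], got {self.completeness_pct}"
            )
        if self.depth_m is not None and self.depth_m < 0:
            raise ValidationError(f"{self.genome_id}: negative depth {self.depth_m}")


def metadata_to_frame(records: Sequence[GenomeMetadata]) -> pd.DataFrame:
    rows = []
    for r in records:
        r.validate()
        rows.append({c: getattr(r, c) for c in METADATA_COLUMNS})
    df = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    return df


def frame_to_metadata(df: pd.DataFrame) -> list:
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for c in METADATA_COLUMNS:
            v = row.get(c)
            kwargs[c] = None if (pd.isna(v) if not isinstance(v, str) else False) else v
        if kwargs["completeness_pct"] is None:
            kwargs["completeness_pct"] = 100.0
        rec = GenomeMetadata(**kwargs)
        rec.validate()
        out.append(rec)
    return out


def validate_metadata_frame(df: pd.DataFrame) -> None:
    """Check the frame-level invariants of a metadata table."""
    missing = [c for c in ("genome_id", "ecotype", "completeness_pct") if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    if df["genome_id"].duplicated().any():
        dupes = df.loc[df["genome_id"].duplicated(), "genome_id"].tolist()
        raise ValidationError(f"duplicate genome ids in metadata: {dupes[:5]}")
    comp = pd.to_numeric(df["completeness_pct"], errors="coerce")
    bad = df.loc[~((comp > 0) & (comp <= 100)), "genome_id"].tolist()
    if bad:
        raise ValidationError(f"completeness_pct outside (0, 100] for genomes: {bad[:5]}")
    labeled = df["ecotype"].notna()
    bad_eco = df.loc[labeled & ~df["ecotype"].isin(ECOTYPES), "genome_id"].tolist()
    if bad_eco:
        raise ValidationError(f"unknown ecotype labels for genomes: {bad_eco[:5]}")
    if "clade" in df.columns:
        has_both = labeled & df["clade"].notna()
        pref = df.loc[has_both].apply(lambda r: str(r["clade"]).startswith(r["ecotype"]), axis=1)
        bad_clade = df.loc[has_both][~pref]["genome_id"].tolist() if len(pref) else []
        if bad_clade:
            raise ValidationError(f"clade/ecotype prefix mismatch for genomes: {bad_clade[:5]}")
    if "depth_m" in df.columns:
        depth = pd.to_numeric(df["depth_m"], errors="coerce")
        bad_depth = df.loc[depth < 0, "genome_id"].tolist()
        if bad_depth:
            raise ValidationError(f"negative depth for genomes: {bad_depth[:5]}")


@dataclass
class ANITable:
    """Pairwise ANI records: columns query, reference, ani_pct, mapped, total.

    ``ani_pct`` is NaN for censored pairs (values the reporting tool would not
    emit because they fall at or below its ~75% floor).
    """

    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ["query", "reference", "ani_pct", "mapped", "total"]

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            self.records = pd.DataFrame(columns=self.COLUMNS)
        missing = [c for c in ("query", "reference", "ani_pct") if c not in self.records.columns]
        if missing:
            raise ValidationError(f"ANI table missing columns: {missing}")
        ani = pd.to_numeric(self.records["ani_pct"], errors="coerce")
        reported = ani.dropna()
        if ((reported < 0) | (reported > 100)).any():
            raise ValidationError("ANI values must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.records)

    def reported(self) -> pd.DataFrame:
        """Rows with a non-censored ANI value."""
        return self.records[self.records["ani_pct"].notna()]


@dataclass
class Dataset:
    """A matrix + metadata (+ optional ANI) bundle with cross-references checked."""

    matrix: GeneClusterMatrix
    metadata: pd.DataFrame
    ani: Optional[ANITable] = None

    def __post_init__(self) -> None:
        validate_metadata_frame(self.metadata)
        meta_ids = set(self.metadata["genome_id"])
        missing = [g for g in self.matrix.genome_ids if g not in meta_ids]
        if missing:
            raise ValidationError(f"matrix genomes missing from metadata: {missing[:5]}")
        if self.ani is not None and len(self.ani):
            matrix_ids = set(self.matrix.genome_ids)
            ani_ids = set(self.ani.records["query"]) | set(self.ani.records["reference"])
            stray = sorted(ani_ids - matrix_ids)
            if stray:
                raise ValidationError(f"ANI genomes not in matrix: {stray[:5]}")
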