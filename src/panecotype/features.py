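"""Feature-space reductions for the pangenome matrix.

Two stages, mirroring how an oversized accessory-gene feature space is tamed
before modeling:

1. an ecotype-conditional frequency filter — a gene cluster is removed iff
   its prevalence is below the cutoff (default 5%) in *both* ecotypes;
2. a linear projection (PCA, default 50 components) fitted on training
   genomes only and applied to held-out genomes.

Binary features are centered but not variance-scaled before projection, and
component signs are fixed (largest-magnitude loading positive) so results
are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .types import GeneClusterMatrix, ValidationError

__all__ = ["ReductionReport", "ProjectionModel", "reduce_by_frequency",
           "fit_projection", "transform"]


@dataclass
class ReductionReport:
    kept_cluster_ids: list
    removed_cluster_ids: list
    prevalence: pd.DataFrame  # per-cluster HL/LL prevalence + kept flag
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return self.prevalence


def reduce_by_frequency(matrix: GeneClusterMatrix, metadata: pd.DataFrame,
                        cutoff: float = 0.05):
    """Drop clusters rare in both ecotypes.

    A cluster is kept iff its prevalence is ``>= cutoff`` in HL genomes or
    ``>= cutoff`` in LL genomes (removal is strict-below in both, so exactly
    at the cutoff is kept).  Prevalences are computed on the supplied genome
    set only.  Idempotent.
    """
    eco = metadata.set_index("genome_id").loc[matrix.genome_ids, "ecotype"]
    if eco.isna().any():
        bad = eco.index[eco.isna()].tolist()
        raise ValidationError(f"reduce_by_frequency: genomes without ecotype: {bad[:5]}")
    present = set(eco.unique())
    if present != {"HL", "LL"}:
        raise ValidationError(
            f"reduce_by_frequency needs both ecotypes in the genome set, got {sorted(present)}"
        )
    hl = (eco == "HL").to_numpy()
    prev_hl = matrix.prevalence(hl)
    prev_ll = matrix.prevalence(~hl)
    kept = (prev_hl >= cutoff) | (prev_ll >= cutoff)
    ids = np.asarray(matrix.cluster_ids, dtype=object)
    report = ReductionReport(
        kept_cluster_ids=list(ids[kept]),
        removed_cluster_ids=list(ids[~kept]),
        prevalence=pd.DataFrame({
            "cluster_id": ids,
            "prevalence_hl": prev_hl,
            "prevalence_ll": prev_ll,
            "kept": kept,
        }),
        cutoff=cutoff,
    )
    reduced = GeneClusterMatrix(matrix.genome_ids, list(ids[kept]), matrix.presence[:, kept])
    return reduced, report


@dataclass
class ProjectionModel:
    """Centered linear projection of the binary feature space."""

    n_components: int
    loadings: np.ndarray  # components x features
    mean: np.ndarray      # training-set feature means
    cluster_ids: list
    explained_variance_ratio: np.ndarray

    def save(self, path) -> None:
        np.savez_compressed(path, loadings=self.loadings, mean=self.mean,
                            cluster_ids=np.array(self.cluster_ids, dtype=object),
                            explained_variance_ratio=self.explained_variance_ratio)

    @classmethod
    def load(cls, path) -> "ProjectionModel":
        d = np.load(path, allow_pickle=True)
        return cls(n_components=d["loadings"].shape[0], loadings=d["loadings"],
                   mean=d["mean"], cluster_ids=list(d["cluster_ids"]),
                   explained_variance_ratio=d["explained_variance_ratio"])


def fit_projection(train_matrix: GeneClusterMatrix, n_components: int = 50) -> ProjectionModel:
    """Fit the projection on training genomes only.

    Raises if ``n_components`` exceeds the rank bound
    ``min(n_train_genomes, n_features)``.
    """
    n, p = train_matrix.presence.shape
    if n_components > min(n, p):
        raise ValidationError(
            f"n_components={n_components} exceeds rank bound min({n}, {p})"
        )
    X = train_matrix.presence.astype(np.float64)
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    loadings = pca.components_.copy()
    # deterministic sign: make each component's largest-magnitude entry positive
    for k in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
    return ProjectionModel(
        n_components=n_components,
        loadings=loadings,
        mean=pca.mean_.copy(),
        cluster_ids=list(train_matrix.cluster_ids),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def transform(model: ProjectionModel, matrix: GeneClusterMatrix) -> np.ndarray:
    """Project genome vectors: centered by the *training* mean, then rotated."""
    if list(matrix.cluster_ids) != list(model.cluster_ids):
        raise ValidationError("matrix cluster ids do not match the fitted projection")
    X = matrix.presence.astype(np.float64)
    return (X - model.mean) @ model.loadings.T
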