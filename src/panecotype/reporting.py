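"""2-D embeddings, separation scores and summary figures/tables.

The genome collection is embedded with UMAP on the Jaccard distance between
binary gene-content profiles (computed exactly via dot products and passed
as a precomputed metric, which also makes the embedding reproducible from a
seed).  Separation under a labeling is quantified as the mean silhouette.
The report renderer writes whatever panels its inputs allow and skips the
rest with a log line.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
from sklearn.metrics import silhouette_score

from .types import ANITable, GeneClusterMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["EmbeddingResult", "jaccard_distance_matrix", "embed",
           "separation_score", "render_report"]


@dataclass
class EmbeddingResult:
    genome_ids: list
    coordinates: np.ndarray          # genomes x 2
    params: dict
    separation: Dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"genome_id": self.genome_ids,
                             "umap1": self.coordinates[:, 0],
                             "umap2": self.coordinates[:, 1]})


def jaccard_distance_matrix(matrix: GeneClusterMatrix) -> np.ndarray:
    """Exact pairwise Jaccard distances on binary profiles via dot products.

    Pairs of identical profiles (including two all-zero genomes) get
    distance 0.
    """
    X = matrix.presence.astype(np.float32)
    inter = X @ X.T
    sizes = np.diag(inter).copy()
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        D = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 1.0)


def embed(matrix: GeneClusterMatrix, n_neighbors: int = 15, min_dist: float = 0.1,
          seed: int = 0, metadata: Optional[pd.DataFrame] = None) -> EmbeddingResult:
    """UMAP 2-D embedding of gene content under Jaccard dissimilarity.

    Deterministic for a given seed.  A neighbor count that exceeds the
    collection size is clamped with a warning; a degenerate collection
    (all genomes identical) still embeds, with a warning and a
    near-zero separation score.
    """
    n = matrix.n_genomes
    if n < 10:
        raise ValidationError(f"embedding needs >= 10 genomes, got {n}")
    if n_neighbors >= n:
        logger.warning("n_neighbors=%d clamped to %d (collection size)", n_neighbors, n - 1)
        n_neighbors = n - 1
    D = jaccard_distance_matrix(matrix)
    if np.allclose(D, 0.0):
        logger.warning("all genomes have identical gene content; embedding is degenerate")
    import umap  # deferred: numba-jitted import is slow

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            min_dist=min_dist, metric="precomputed",
                            random_state=seed)
        coords = reducer.fit_transform(D)
    result = EmbeddingResult(
        genome_ids=list(matrix.genome_ids),
        coordinates=np.asarray(coords, dtype=float),
        params={"n_neighbors": n_neighbors, "min_dist": min_dist,
                "metric": "jaccard", "seed": seed},
    )
    if metadata is not None:
        meta = metadata.set_index("genome_id").loc[matrix.genome_ids]
        for channel in ("ecotype", "clade"):
            labels = meta[channel]
            if labels.notna().all() and labels.nunique() >= 2:
                try:
                    result.separation[channel] = separation_score(
                        result.coordinates, labels.to_numpy())
                except ValidationError:
                    pass
    return result


def separation_score(coords_or_distance: np.ndarray, labels: Sequence,
                     precomputed: bool = False) -> float:
    """Mean silhouette of a labeling, in [-1, 1].

    Accepts either 2-D coordinates (euclidean silhouette) or a precomputed
    distance matrix.  Singleton classes are excluded with a warning;
    invariant under renaming of labels.
    """
    labels = np.asarray(labels)
    X = np.asarray(coords_or_distance, dtype=float)
    vals, counts = np.unique(labels, return_counts=True)
    keep_classes = vals[counts >= 2]
    dropped = vals[counts < 2]
    if len(dropped):
        logger.warning("singleton classes excluded from silhouette: %s", list(dropped))
    mask = np.isin(labels, keep_classes)
    if len(keep_classes) < 2:
        raise ValidationError("need >= 2 classes with >= 2 members for a separation score")
    labels = labels[mask]
    if precomputed:
        X = X[np.ix_(mask, mask)]
        if np.allclose(X, 0.0):
            return 0.0
        return float(silhouette_score(X, labels, metric="precomputed"))
    X = X[mask]
    if np.allclose(X, X[0]):
        return 0.0
    return float(silhouette_score(X, labels))


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def _ani_heatmap(ax, ani: ANITable, order: pd.DataFrame, title: str) -> None:
    ids = order["genome_id"].tolist()
    idx = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    M = np.full((n, n), np.nan)
    rep = ani.records
    qi = rep["query"].map(idx)
    ri = rep["reference"].map(idx)
    ok = qi.notna() & ri.notna()
    M[qi[ok].astype(int), ri[ok].astype(int)] = rep.loc[ok, "ani_pct"]
    im = ax.imshow(M, cmap="viridis", interpolation="nearest")  # NaN renders blank
    ax.set_title(title, fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])
    plt.colorbar(im, ax=ax, fraction=0.046, label="ANI %")


def render_report(outdir, matrix: Optional[GeneClusterMatrix] = None,
                  metadata: Optional[pd.DataFrame] = None,
                  embedding: Optional[EmbeddingResult] = None,
                  ani: Optional[ANITable] = None,
                  model_records: Optional[pd.DataFrame] = None,
                  consensus_table: Optional[pd.DataFrame] = None,
                  predictions: Optional[pd.DataFrame] = None) -> list:
    """Write figures and tables for whatever stage outputs are available.

    Returns the list of files written.  Missing inputs skip their panels
    with a log message; the call still succeeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _save(fig, name):
        path = outdir / name
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    if embedding is not None and metadata is not None:
        meta = metadata.set_index("genome_id").reindex(embedding.genome_ids)
        channels = [("ecotype", "categorical"), ("clade", "categorical"),
                    ("depth_m", "continuous"), ("completeness_pct", "continuous")]
        if predictions is not None and len(predictions):
            pred = (predictions.groupby("genome_id")["prediction"].mean() >= 0.5)
            meta = meta.assign(predicted_class=pred.reindex(meta.index)
                               .map({True: "HL", False: "LL"}))
            channels.append(("predicted_class", "categorical"))
        have = [(c, k) for c, k in channels if c in meta and meta[c].notna().any()]
        for c, kind in channels:
            if (c, kind) not in have:
                logger.info("embedding overlay %s skipped: no values", c)
        if have:
            fig, axes = plt.subplots(1, len(have), figsize=(4 * len(have), 3.6))
            axes = np.atleast_1d(axes)
            for ax, (c, kind) in zip(axes, have):
                x, y = embedding.coordinates[:, 0], embedding.coordinates[:, 1]
                if kind == "categorical":
                    for v in sorted(meta[c].dropna().unique()):
                        m = (meta[c] == v).to_numpy()
                        ax.scatter(x[m], y[m], s=8, label=str(v))
                    ax.legend(fontsize=6, markerscale=1.5)
                else:
                    sc = ax.scatter(x, y, c=meta[c], s=8, cmap="viridis")
                    plt.colorbar(sc, ax=ax, fraction=0.046)
                ax.set_title(c, fontsize=9)
                ax.set_xticks([]); ax.set_yticks([])
            _save(fig, "embedding_overlays.png")
        embedding.to_frame().to_csv(outdir / "embedding_coordinates.csv", index=False)
        written.append(outdir / "embedding_coordinates.csv")
    else:
        logger.info("embedding panels skipped")

    if ani is not None and metadata is not None and len(ani):
        fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
        by_depth = metadata.sort_values(["ecotype", "depth_m"], na_position="last")
        by_clade = metadata.sort_values(["ecotype", "clade"], na_position="last")
        _ani_heatmap(axes[0], ani, by_depth, "ANI ordered by (ecotype, depth)")
        _ani_heatmap(axes[1], ani, by_clade, "ANI ordered by (ecotype, clade)")
        _save(fig, "ani_heatmaps.png")
    else:
        logger.info("ANI panels skipped")

    if metadata is not None:
        from .ecostats import GENOME_METRICS
        have_metrics = [m for m in GENOME_METRICS
                        if m in metadata and metadata[m].notna().any()]
        if have_metrics and metadata["clade"].notna().any():
            fig, axes = plt.subplots(1, len(have_metrics), figsize=(3.2 * len(have_metrics), 3.4))
            axes = np.atleast_1d(axes)
            clades = sorted(metadata["clade"].dropna().unique())
            for ax, m in zip(axes, have_metrics):
                data = [metadata.loc[metadata["clade"] == c, m].dropna() for c in clades]
                ax.boxplot(data, tick_labels=clades)
                ax.set_title(m, fontsize=9)
                ax.tick_params(axis="x", rotation=60, labelsize=6)
            _save(fig, "metric_boxplots.png")

    if model_records is not None and len(model_records):
        summary = (model_records.groupby(["model_kind", "feature_space"])["test_score"]
                   .agg(["mean", "median", "std", "min", "max"]).reset_index())
        summary.to_csv(outdir / "model_performance_summary.csv", index=False)
        written.append(outdir / "model_performance_summary.csv")
        fig, ax = plt.subplots(figsize=(5, 3.4))
        keys = list(model_records.groupby(["model_kind", "feature_space"]).groups)
        data = [model_records[(model_records["model_kind"] == k) &
                              (model_records["feature_space"] == s)]["test_score"]
                for k, s in keys]
        ax.boxplot(data, tick_labels=[f"{k}\n{s}" for k, s in keys])
        ax.set_ylabel("test score")
        _save(fig, "model_performance.png")
    else:
        logger.info("model panels skipped")

    if consensus_table is not None and len(consensus_table):
        consensus_table.to_csv(outdir / "consensus_features.csv", index=False)
        written.append(outdir / "consensus_features.csv")

    index = outdir / "index.md"
    with open(index, "w") as fh:
        fh.write("# Run report\n\nFiles:\n")
        for f in written:
            fh.write(f"- {Path(f).name}\n")
        if embedding is not None:
            fh.write(f"\nEmbedding parameters: {embedding.params}\n")
            if embedding.separation:
                fh.write(f"Separation scores: {embedding.separation}\n")
    written.append(index)
    return [Path(p) for p in written]
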