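"""File-based pipeline stages used by the command-line interface.

Each stage reads the artifacts of upstream stages from a run directory,
computes, and writes its own artifacts plus a small log entry.  Stages are
deterministic for a given resolved configuration, so re-running a stage
reproduces its outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, save_pipeline_config, _to_plain
from .consensus import consensus
from .ecostats import ani_within_between, fisher_per_cluster, metric_tests
from .features import reduce_by_frequency
from .models import (ModelRunResult, run_label_permutations,
                     stratify_by_completeness, train_evaluate)
from .pangenome_io import (read_fastani, read_metadata, read_rtab,
                           write_fastani, write_metadata, write_rtab)
from .reporting import embed, render_report
from .synth import apply_dropout, simulate_collection

logger = logging.getLogger(__name__)


class MissingArtifactError(FileNotFoundError):
    """An upstream artifact required by a stage is absent."""


def _require(path: Path) -> Path:
    if not path.exists():
        raise MissingArtifactError(f"missing upstream artifact: {path}")
    return path


def _log_stage(outdir: Path, stage: str, cfg: PipelineConfig, extra=None) -> None:
    payload = json.dumps(_to_plain(cfg), sort_keys=True).encode()
    entry = {
        "stage": stage,
        "version": __version__,
        "config_sha1": hashlib.sha1(payload).hexdigest(),
        "seed": cfg.seed,
    }
    if extra:
        entry.update(extra)
    with open(outdir / "run_log.jsonl", "a") as fh:
        fh.write(json.dumps(entry) + "\n")


def _split(metadata: pd.DataFrame, cfg: PipelineConfig):
    return stratify_by_completeness(metadata, cfg.train_threshold,
                                    cfg.completeness_floor, cfg.cv_folds,
                                    cfg.resamples, cfg.seed)


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, metadata, ani = simulate_collection(cfg.simulation)
    write_rtab(matrix, outdir / "pangenome.rtab")
    if cfg.simulation.dropout_mode == "bernoulli":
        observed = apply_dropout(matrix, metadata, seed=cfg.simulation.seed + 5)
        write_rtab(observed, outdir / "pangenome_observed.rtab")
    write_metadata(metadata, outdir / "metadata.csv")
    write_fastani(ani, outdir / "ani.tsv")
    save_pipeline_config(cfg, outdir / "config.resolved.yaml")
    _log_stage(outdir, "simulate", cfg,
               {"n_genomes": matrix.n_genomes, "n_clusters": matrix.n_clusters})


def _load_matrix(outdir: Path, observed: bool = True):
    obs = outdir / "pangenome_observed.rtab"
    path = obs if (observed and obs.exists()) else outdir / "pangenome.rtab"
    return read_rtab(_require(path))


def stage_reduce(cfg: PipelineConfig, outdir: Path) -> None:
    matrix = _load_matrix(outdir)
    metadata = read_metadata(_require(outdir / "metadata.csv"))
    labeled = metadata.loc[metadata["has_ecotype"], "genome_id"].tolist()
    reduced, report = reduce_by_frequency(matrix.subset_genomes(labeled), metadata,
                                          cfg.reduction_cutoff)
    write_rtab(reduced, outdir / "pangenome_reduced.rtab")
    report.to_frame().to_csv(outdir / "reduction_report.csv", index=False)
    _log_stage(outdir, "reduce", cfg, {"kept": len(report.kept_cluster_ids)})


def stage_train(cfg: PipelineConfig, outdir: Path, model_kind: str = "RF",
                feature_space: str = "full", task: str = "ecotype") -> ModelRunResult:
    matrix = _load_matrix(outdir)
    metadata = read_metadata(_require(outdir / "metadata.csv"))
    plan = _split(metadata, cfg)
    result = train_evaluate(matrix, metadata, plan, model_kind, feature_space, task,
                            cfg.model, cfg.reduction_cutoff, cfg.n_components)
    tag = f"{task}_{model_kind}_{feature_space}".lower()
    result.records.assign(model_kind=model_kind, feature_space=feature_space) \
        .to_csv(outdir / f"model_records_{tag}.csv", index=False)
    result.predictions.to_csv(outdir / f"model_predictions_{tag}.csv", index=False)
    np.savez_compressed(outdir / f"model_importances_{tag}.npz",
                        importances=result.importances,
                        ids=np.array(result.importance_ids, dtype=object))
    _log_stage(outdir, f"train:{tag}", cfg,
               {"mean_test_score": float(result.records["test_score"].mean())})
    return result


def stage_permute(cfg: PipelineConfig, outdir: Path, model_kind: str = "LR",
                  task: str = "ecotype") -> pd.DataFrame:
    matrix = _load_matrix(outdir)
    metadata = read_metadata(_require(outdir / "metadata.csv"))
    plan = _split(metadata, cfg)
    records = run_label_permutations(matrix, metadata, plan, cfg.n_permutations,
                                     model_kind, task, cfg.model)
    records.to_csv(outdir / f"permutation_records_{task}_{model_kind}.csv".lower(), index=False)
    _log_stage(outdir, "permute", cfg,
               {"mean_score": float(records["test_score"].mean())})
    return records


def _load_result(outdir: Path, model_kind: str, feature_space: str,
                 task: str = "ecotype") -> ModelRunResult:
    tag = f"{task}_{model_kind}_{feature_space}".lower()
    records = pd.read_csv(_require(outdir / f"model_records_{tag}.csv"))
    predictions = pd.read_csv(_require(outdir / f"model_predictions_{tag}.csv"))
    dat = np.load(_require(outdir / f"model_importances_{tag}.npz"), allow_pickle=True)
    return ModelRunResult(model_kind=model_kind, feature_space=feature_space, task=task,
                          records=records, predictions=predictions,
                          importances=dat["importances"], importance_ids=list(dat["ids"]))


def stage_consensus(cfg: PipelineConfig, outdir: Path,
                    feature_space: str = "full") -> pd.DataFrame:
    matrix = _load_matrix(outdir)
    metadata = read_metadata(_require(outdir / "metadata.csv"))
    results = [_load_result(outdir, kind, feature_space) for kind in ("RF", "LR")]
    table = consensus(results, matrix, metadata, cfg.consensus_top_k,
                      cfg.consensus_min_frequency, cfg.consensus_require_both)
    table.to_csv(outdir / "consensus_features.csv", index=False)
    _log_stage(outdir, "consensus", cfg, {"n_features": len(table)})
    return table


def stage_stats(cfg: PipelineConfig, outdir: Path) -> None:
    matrix = _load_matrix(outdir, observed=False)
    metadata = read_metadata(_require(outdir / "metadata.csv"))
    labeled = metadata.loc[metadata["has_ecotype"], "genome_id"].tolist()
    fisher = fisher_per_cluster(matrix.subset_genomes(labeled), metadata)
    fisher.to_csv(outdir / "fisher_results.csv", index=False)
    report = metric_tests(metadata, min_group=cfg.stats_min_group)
    report.ecotype_tests.to_csv(outdir / "metric_ecotype_tests.csv", index=False)
    report.clade_tests.to_csv(outdir / "metric_clade_tests.csv", index=False)
    report.dunn_tests.to_csv(outdir / "metric_dunn_tests.csv", index=False)
    extra = {"fisher_significant": int((fisher["p_adjusted"] < cfg.stats_alpha).sum()),
             "fisher_infinite_or": int(fisher["infinite_or"].sum())}
    ani_path = outdir / "ani.tsv"
    if ani_path.exists():
        comparison = ani_within_between(read_fastani(ani_path), metadata)
        with open(outdir / "ani_comparison.json", "w") as fh:
            json.dump({"within_median_pct": comparison.within_median_pct,
                       "between_median_pct": comparison.between_median_pct,
                       "statistic": comparison.statistic,
                       "p_value": comparison.p_value,
                       "n_within": len(comparison.within_values),
                       "n_between": len(comparison.between_values)}, fh, indent=2)
        extra["ani_within_median"] = comparison.within_median_pct
        extra["ani_between_median"] = comparison.between_median_pct
    else:
        logger.info("no ANI table; ANI comparison skipped")
    _log_stage(outdir, "stats", cfg, extra)


def stage_embed(cfg: PipelineConfig, outdir: Path) -> None:
    matrix = _load_matrix(outdir)
    metadata = read_metadata(_require(outdir / "metadata.csv"))
    result = embed(matrix, cfg.embed_neighbors, cfg.embed_min_dist,
                   seed=cfg.seed, metadata=metadata)
    result.to_frame().to_csv(outdir / "embedding.csv", index=False)
    with open(outdir / "embedding_params.json", "w") as fh:
        json.dump({**result.params, "separation": result.separation}, fh, indent=2)
    _log_stage(outdir, "embed", cfg, {"separation": result.separation})


def stage_report(cfg: PipelineConfig, outdir: Path) -> None:
    metadata = read_metadata(_require(outdir / "metadata.csv"))
    embedding = None
    emb_path = outdir / "embedding.csv"
    if emb_path.exists():
        df = pd.read_csv(emb_path)
        from .reporting import EmbeddingResult
        with open(outdir / "embedding_params.json") as fh:
            params = json.load(fh)
        embedding = EmbeddingResult(df["genome_id"].tolist(),
                                    df[["umap1", "umap2"]].to_numpy(),
                                    params, params.pop("separation", {}))
    ani = read_fastani(outdir / "ani.tsv") if (outdir / "ani.tsv").exists() else None
    record_files = sorted(outdir.glob("model_records_*.csv"))
    model_records = (pd.concat([pd.read_csv(f) for f in record_files], ignore_index=True)
                     if record_files else None)
    pred_files = sorted(outdir.glob("model_predictions_ecotype_*.csv"))
    predictions = (pd.read_csv(pred_files[0]) if pred_files else None)
    cons_path = outdir / "consensus_features.csv"
    consensus_table = pd.read_csv(cons_path) if cons_path.exists() else None
    render_report(outdir / "report", metadata=metadata, embedding=embedding, ani=ani,
                  model_records=model_records, consensus_table=consensus_table,
                  predictions=predictions)
    _log_stage(outdir, "report", cfg)


def run_all(cfg: PipelineConfig, outdir: Path) -> None:
    stage_simulate(cfg, outdir)
    stage_reduce(cfg, outdir)
    for kind in ("RF", "LR"):
        stage_train(cfg, outdir, model_kind=kind, feature_space="full")
    stage_permute(cfg, outdir)
    stage_consensus(cfg, outdir)
    stage_stats(cfg, outdir)
    stage_embed(cfg, outdir)
    stage_report(cfg, outdir)
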