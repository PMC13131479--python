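"""Cross-run consensus of important features.

A feature earns a place on the high-confidence ecotype-marker list by
appearing in the top-k importances of a large fraction of fits (resamples x
folds), in every required model family.  The output carries per-ecotype
prevalences and a mutually-exclusive flag (present in one ecotype, absent in
the other) for downstream interpretation.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .models import ModelRunResult
from .types import GeneClusterMatrix

logger = logging.getLogger(__name__)

__all__ = ["rank_features", "consensus"]


def rank_features(result: ModelRunResult, top_k: int = 20) -> List[List[str]]:
    """Per-fit top-k feature ids, highest importance first.

    Ties break lexicographically on feature id so ranking is deterministic.
    ``top_k`` larger than the feature count is clamped with a warning;
    ``top_k == 0`` yields empty lists.
    """
    ids = np.asarray(result.importance_ids, dtype=object)
    p = len(ids)
    if top_k > p:
        logger.warning("top_k=%d clamped to feature count %d", top_k, p)
        top_k = p
    out: List[List[str]] = []
    lex = np.argsort(ids, kind="stable")  # id order as the tie-break baseline
    for imp in result.importances:
        order = lex[np.argsort(-imp[lex], kind="stable")]
        out.append(list(ids[order[:top_k]]))
    return out


def consensus(results: Sequence[ModelRunResult], matrix: GeneClusterMatrix,
              metadata: pd.DataFrame, top_k: int = 20,
              min_frequency: float = 0.8, require_both_models: bool = True) -> pd.DataFrame:
    """Aggregate top-k lists across fits and model families.

    A feature is kept iff its top-k appearance frequency is
    ``>= min_frequency`` within *every* required model family ("required"
    meaning every family present in ``results`` when
    ``require_both_models``, otherwise any one family suffices).  Output is
    sorted by (min cross-family frequency, mean importance) descending and
    annotated with HL/LL prevalences and the mutually-exclusive flag.
    """
    by_kind: Dict[str, List[ModelRunResult]] = {}
    for r in results:
        by_kind.setdefault(r.model_kind, []).append(r)
    if require_both_models and len(by_kind) < 2:
        raise ValueError("require_both_models needs results from >=2 model families")

    freq: Dict[str, Dict[str, float]] = {}
    mean_imp: Dict[str, Dict[str, float]] = {}
    for kind, kind_results in by_kind.items():
        counts: Dict[str, int] = {}
        n_fits = 0
        imp_sum: Dict[str, float] = {}
        for res in kind_results:
            lists = rank_features(res, top_k)
            n_fits += len(lists)
            for fit_list in lists:
                for f in fit_list:
                    counts[f] = counts.get(f, 0) + 1
            ids = np.asarray(res.importance_ids, dtype=object)
            totals = res.importances.sum(axis=0)
            for f, v in zip(ids, totals):
                imp_sum[f] = imp_sum.get(f, 0.0) + float(v)
        freq[kind] = {f: c / n_fits for f, c in counts.items()} if n_fits else {}
        mean_imp[kind] = {f: v / n_fits for f, v in imp_sum.items()} if n_fits else {}

    kinds = sorted(by_kind)
    candidates = set()
    for kind in kinds:
        candidates |= set(freq[kind])

    kept = []
    for f in candidates:
        fs = [freq[kind].get(f, 0.0) for kind in kinds]
        ok = all(v >= min_frequency for v in fs) if require_both_models \
            else any(v >= min_frequency for v in fs)
        if ok:
            kept.append((f, min(fs), float(np.mean([mean_imp[k].get(f, 0.0) for k in kinds]))))

    eco = metadata.set_index("genome_id").loc[matrix.genome_ids, "ecotype"]
    hl_mask = (eco == "HL").to_numpy()
    col = {c: j for j, c in enumerate(matrix.cluster_ids)}
    rows = []
    for f, fmin, imp in kept:
        if f in col:
            v = matrix.presence[:, col[f]]
            prev_hl = float(v[hl_mask].mean()) if hl_mask.any() else np.nan
            prev_ll = float(v[~hl_mask].mean()) if (~hl_mask).any() else np.nan
        else:  # projected components have no single cluster
            prev_hl = prev_ll = np.nan
        mutually_exclusive = (
            (prev_hl == 0 and prev_ll > 0) or (prev_ll == 0 and prev_hl > 0)
            if not (np.isnan(prev_hl) or np.isnan(prev_ll)) else False
        )
        rows.append({
            "cluster_id": f, "frequency": fmin, "mean_importance": imp,
            "model_kinds": ",".join(k for k in kinds if freq[k].get(f, 0.0) >= min_frequency),
            "prevalence_hl": prev_hl, "prevalence_ll": prev_ll,
            "mutually_exclusive": bool(mutually_exclusive),
        })
    out = pd.DataFrame(rows, columns=["cluster_id", "frequency", "mean_importance",
                                      "model_kinds", "prevalence_hl", "prevalence_ll",
                                      "mutually_exclusive"])
    if len(out):
        out = out.sort_values(["frequency", "mean_importance"],
                              ascending=False, kind="stable").reset_index(drop=True)
    return out
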