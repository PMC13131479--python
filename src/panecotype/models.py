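"""Completeness-stratified supervised evaluation.

Training uses only high-completeness genomes (completeness > 75%) with
5-fold cross-validation and 10 randomly seeded resamples; every fold's
fitted model is additionally scored on the fragmented test stratum
(completeness 25-75%).  Classification (ecotype) is optimized and reported
as the Matthews correlation coefficient (MCC); regression (depth of
isolation) as RMSE in meters.  A balance-preserving label-permutation null
quantifies how much apparent skill survives when the genotype-phenotype link
is severed.

Model families: random forests (impurity importances) and elastic-net
penalized linear models (importance = |coefficient| x feature SD on the
training stratum).  Hyper-parameters are tuned on the CV folds; grid ties
resolve to the first grid entry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from .config import ModelConfig
from .features import fit_projection, reduce_by_frequency, transform
from .types import GeneClusterMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan", "ModelRunResult", "PermutationRecord",
    "stratify_by_completeness", "mcc", "rmse",
    "train_evaluate", "permute_labels", "run_label_permutations",
    "correctness_performance_correlation",
]


# ---------------------------------------------------------------------------
# split plan
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    train_ids: list
    test_ids: list
    excluded_ids: list
    cv_folds: int = 5
    resamples: int = 10
    seed: int = 0


def stratify_by_completeness(metadata: pd.DataFrame, train_threshold: float = 75.0,
                             floor: float = 25.0, cv_folds: int = 5,
                             resamples: int = 10, seed: int = 0) -> SplitPlan:
    """Assign genomes to train / test / excluded strata by completeness.

    Train iff completeness > ``train_threshold``; test iff
    ``floor <= completeness <= train_threshold`` (both endpoints land in the
    test stratum); excluded otherwise.  Genomes without an ecotype label are
    excluded from the supervised strata.
    """
    comp = pd.to_numeric(metadata["completeness_pct"], errors="coerce")
    if comp.isna().any():
        bad = metadata.loc[comp.isna(), "genome_id"].tolist()
        raise ValidationError(f"completeness missing for genomes: {bad[:5]}")
    labeled = metadata["ecotype"].notna()
    train = labeled & (comp > train_threshold)
    test = labeled & (comp >= floor) & (comp <= train_threshold)
    excluded = ~(train | test)
    plan = SplitPlan(
        train_ids=metadata.loc[train, "genome_id"].tolist(),
        test_ids=metadata.loc[test, "genome_id"].tolist(),
        excluded_ids=metadata.loc[excluded, "genome_id"].tolist(),
        cv_folds=cv_folds, resamples=resamples, seed=seed,
    )
    if not plan.train_ids:
        raise ValidationError("empty training stratum (no genomes above the threshold)")
    if not plan.test_ids:
        raise ValidationError("empty test stratum (no genomes in the intermediate band)")
    return plan


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient from confusion counts.

    If any denominator factor is zero (e.g. all predictions one class) the
    convention is 0.  An all-zero confusion table is an error.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    if tp + tn + fp + fn == 0:
        raise ValueError("empty confusion table")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _mcc_from_vectors(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return mcc(tp, tn, fp, fn)


def rmse(predicted: Sequence[float], truth: Sequence[float]) -> float:
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {truth.shape}")
    if predicted.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((predicted - truth) ** 2)))


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class ModelRunResult:
    model_kind: str          # "RF" | "LR"
    feature_space: str       # "full" | "reduced" | "projected"
    task: str                # "ecotype" | "depth"
    records: pd.DataFrame    # one row per (resample, fold)
    predictions: pd.DataFrame  # test-stratum predictions per fit
    importances: np.ndarray  # fits x features
    importance_ids: list     # feature ids for the importance columns

    def validate(self) -> None:
        if self.task == "ecotype":
            if ((self.records["test_score"] < -1) | (self.records["test_score"] > 1)).any():
                raise ValidationError("MCC outside [-1, 1]")
        else:
            if (self.records["test_score"] < 0).any():
                raise ValidationError("negative RMSE")


@dataclass
class PermutationRecord:
    permutation: int
    seed: int
    fraction_correct: float
    test_score: float


# ---------------------------------------------------------------------------
# feature-space preparation
# ---------------------------------------------------------------------------

def _prepare_space(matrix: GeneClusterMatrix, metadata: pd.DataFrame,
                   plan: SplitPlan, feature_space: str,
                   reduction_cutoff: float, n_components: int):
    """Return (X_train, X_test, feature_ids, projector) for the chosen space.

    'full' and 'reduced' are shared across resamples; the projection for
    'projected' is refit per resample on the training stratum (see
    :func:`train_evaluate`), so this returns the reduced matrices plus a
    factory in that case.
    """
    ids = plan.train_ids + plan.test_ids
    if feature_space == "full":
        sub = matrix.subset_genomes(ids)
        return sub, None
    reduced, _ = reduce_by_frequency(matrix.subset_genomes(ids), metadata, reduction_cutoff)
    if feature_space == "reduced":
        return reduced, None
    if feature_space == "projected":
        return reduced, n_components
    raise ValidationError(f"unknown feature space {feature_space!r}")


def _labels(metadata: pd.DataFrame, ids: Sequence, task: str) -> np.ndarray:
    meta = metadata.set_index("genome_id").loc[list(ids)]
    if task == "ecotype":
        eco = meta["ecotype"]
        if eco.isna().any():
            raise ValidationError("ecotype label missing for supervised genomes")
        return (eco == "HL").to_numpy(dtype=int)
    if task == "depth":
        return pd.to_numeric(meta["depth_m"], errors="coerce").to_numpy(dtype=float)
    raise ValidationError(f"unknown task {task!r}")


def _make_estimator(model_kind: str, task: str, param, n_features: int,
                    n_trees: int, l1_ratio: float, seed: int):
    if model_kind == "RF":
        mf = {"sqrt": "sqrt", "p10": max(1, n_features // 10),
              "p3": max(1, n_features // 3)}.get(param, param)
        if task == "ecotype":
            # information-gain splitting: with the 60:40 class imbalance it
            # penalizes impure majority-skewed leaves harder than Gini, which
            # noticeably improves minority-class calls on fragmented genomes
            return RandomForestClassifier(n_estimators=n_trees, max_features=mf,
                                          criterion="entropy", random_state=seed,
                                          n_jobs=1)
        return RandomForestRegressor(n_estimators=n_trees, max_features=mf,
                                     random_state=seed, n_jobs=1)
    if task == "ecotype":
        return LogisticRegression(solver="saga", C=param, l1_ratio=l1_ratio,
                                  max_iter=500, tol=1e-3, random_state=seed)
    return ElasticNet(alpha=param, l1_ratio=l1_ratio, max_iter=5000, random_state=seed)


def _score(task: str, y_true, y_pred) -> float:
    if task == "ecotype":
        return _mcc_from_vectors(np.asarray(y_true), np.asarray(y_pred))
    return rmse(y_pred, y_true)


def _better(task: str, a: float, b: float) -> bool:
    """Is score a better than b (maximize MCC, minimize RMSE)?"""
    return a > b if task == "ecotype" else a < b


def _importance(model, model_kind: str, X_train) -> np.ndarray:
    if model_kind == "RF":
        return model.feature_importances_
    coef = model.coef_.ravel()
    if sp.issparse(X_train):
        Xd = np.asarray(X_train.todense())
    else:
        Xd = np.asarray(X_train, dtype=float)
    std = Xd.std(axis=0)
    return np.abs(coef) * std


def _as_model_input(X: np.ndarray, model_kind: str):
    # linear solvers are much faster on the sparse binary matrix
    if model_kind == "LR" and X.shape[1] > 2000:
        return sp.csr_matrix(X.astype(np.float64))
    return X.astype(np.float32)


# ---------------------------------------------------------------------------
# main evaluation loop
# ---------------------------------------------------------------------------

def train_evaluate(matrix: GeneClusterMatrix, metadata: pd.DataFrame,
                   plan: SplitPlan, model_kind: str = "RF",
                   feature_space: str = "full", task: str = "ecotype",
                   model_config: Optional[ModelConfig] = None,
                   reduction_cutoff: float = 0.05,
                   n_components: int = 50) -> ModelRunResult:
    """Tune, cross-validate and test one model family on one feature space.

    For each resample ``r`` (seed ``plan.seed + r``) the training stratum is
    split into ``plan.cv_folds`` folds; the hyper-parameter grid is scored by
    CV and the best setting refit per fold (full-size forests) and scored on
    (a) the held-out fold and (b) the entire fragmented test stratum.
    Feature importances and test predictions are recorded per fit.
    """
    mc = model_config or ModelConfig()
    base, proj_components = _prepare_space(matrix, metadata, plan, feature_space,
                                           reduction_cutoff, n_components)
    train_mx = base.subset_genomes(plan.train_ids)
    test_mx = base.subset_genomes(plan.test_ids)
    y_train_all = _labels(metadata, plan.train_ids, task)
    y_test = _labels(metadata, plan.test_ids, task)

    if task == "depth":  # genomes without a depth drop out of the regression
        keep_tr = ~np.isnan(y_train_all)
        keep_te = ~np.isnan(y_test)
        train_mx = train_mx.subset_genomes([g for g, k in zip(plan.train_ids, keep_tr) if k])
        test_mx = test_mx.subset_genomes([g for g, k in zip(plan.test_ids, keep_te) if k])
        y_train_all = y_train_all[keep_tr]
        y_test = y_test[keep_te]

    grid = list(mc.rf_feature_grid) if model_kind == "RF" else (
        list(mc.lr_c_grid) if task == "ecotype" else list(mc.en_alpha_grid))

    records, preds, importances, imp_ids = [], [], [], None
    for r in range(plan.resamples):
        seed_r = plan.seed + r
        if proj_components is not None:
            projector = fit_projection(train_mx, proj_components)
            X_tr_full = transform(projector, train_mx)
            X_te_full = transform(projector, test_mx)
            feat_ids = [f"PC{k + 1}" for k in range(proj_components)]
        else:
            X_tr_full = train_mx.presence
            X_te_full = test_mx.presence
            feat_ids = list(train_mx.cluster_ids)
        imp_ids = feat_ids
        p = X_tr_full.shape[1]
        X_tr_in = _as_model_input(np.asarray(X_tr_full), model_kind)
        X_te_in = _as_model_input(np.asarray(X_te_full), model_kind)

        splitter = (StratifiedKFold if task == "ecotype" else KFold)(
            n_splits=plan.cv_folds, shuffle=True, random_state=seed_r)
        split_arg = (X_tr_full, y_train_all) if task == "ecotype" else (X_tr_full,)
        folds = list(splitter.split(*split_arg))

        # ---- grid search on the CV folds (smaller forests for speed) ----
        best_param, best_score = None, None
        for param in grid:
            scores = []
            for tr_idx, va_idx in folds:
                if task == "ecotype" and len(np.unique(y_train_all[tr_idx])) < 2:
                    continue
                est = _make_estimator(model_kind, task, param, p,
                                      mc.tune_trees, mc.l1_ratio, seed_r)
                est.fit(_index_rows(X_tr_in, tr_idx), y_train_all[tr_idx])
                scores.append(_score(task, y_train_all[va_idx],
                                     est.predict(_index_rows(X_tr_in, va_idx))))
            if not scores:
                continue
            mean_score = float(np.mean(scores))
            if best_score is None or _better(task, mean_score, best_score):
                best_param, best_score = param, mean_score
        if best_param is None:
            raise ValidationError("no usable CV fold (degenerate labels in every fold)")

        # ---- final per-fold fits at full forest size --------------------
        for f, (tr_idx, va_idx) in enumerate(folds):
            if task == "ecotype" and len(np.unique(y_train_all[tr_idx])) < 2:
                logger.warning("resample %d fold %d skipped: single-class training fold", r, f)
                continue
            est = _make_estimator(model_kind, task, best_param, p,
                                  mc.n_estimators, mc.l1_ratio, seed_r * 100 + f)
            est.fit(_index_rows(X_tr_in, tr_idx), y_train_all[tr_idx])
            cv_score = _score(task, y_train_all[va_idx],
                              est.predict(_index_rows(X_tr_in, va_idx)))
            y_hat = est.predict(X_te_in)
            test_score = _score(task, y_test, y_hat)
            records.append({
                "resample": r, "fold": f, "seed": seed_r, "param": best_param,
                "cv_score": cv_score, "test_score": test_score,
                "n_train": len(tr_idx), "n_test": len(y_test),
            })
            preds.append(pd.DataFrame({
                "resample": r, "fold": f,
                "genome_id": test_mx.genome_ids,
                "truth": y_test, "prediction": y_hat,
            }))
            importances.append(_importance(est, model_kind, _index_rows(X_tr_in, tr_idx)))

    result = ModelRunResult(
        model_kind=model_kind, feature_space=feature_space, task=task,
        records=pd.DataFrame(records),
        predictions=pd.concat(preds, ignore_index=True),
        importances=np.vstack(importances),
        importance_ids=list(imp_ids),
    )
    result.validate()
    return result


def _index_rows(X, idx):
    return X[idx]


# ---------------------------------------------------------------------------
# label-permutation null
# ---------------------------------------------------------------------------

def permute_labels(labels: Sequence, seed: int) -> Tuple[np.ndarray, float]:
    """Uniform random permutation of the label vector.

    A permutation preserves the class-balance multiset by construction.
    Returns the shuffled vector and the fraction of positions left unchanged.
    """
    labels = np.asarray(labels)
    if labels.size < 2:
        raise ValueError("need at least two labels to permute")
    rng = np.random.default_rng(seed)
    shuffled = labels[rng.permutation(labels.size)]
    fraction_correct = float(np.mean(shuffled == labels))
    return shuffled, fraction_correct


def run_label_permutations(matrix: GeneClusterMatrix, metadata: pd.DataFrame,
                           plan: SplitPlan, n_permutations: int = 50,
                           model_kind: str = "LR", task: str = "ecotype",
                           model_config: Optional[ModelConfig] = None,
                           feature_space: str = "full",
                           reduction_cutoff: float = 0.05,
                           n_components: int = 50) -> pd.DataFrame:
    """Balance-preserving label-permutation null models.

    Permutation ``i`` (seed ``plan.seed + 1000 + i``) uniformly permutes the
    *training-stratum* labels, which preserves the training class balance
    exactly.  The permuted labels are fit with ``plan.cv_folds`` CV-fold
    models (default hyper-parameters — a null needs no grid search), each
    fold model is scored on the fragmented test stratum against the *true*
    labels, and the permutation's record carries the mean of those fold
    scores: how much real predictive signal survives training on mostly
    wrong labels.  ``fraction_correct`` is the proportion of assigned
    (training) labels the shuffle left unchanged.
    """
    mc = model_config or ModelConfig()
    base, proj_components = _prepare_space(matrix, metadata, plan, feature_space,
                                           reduction_cutoff, n_components)
    train_mx = base.subset_genomes(plan.train_ids)
    test_mx = base.subset_genomes(plan.test_ids)
    if proj_components is not None:
        projector = fit_projection(train_mx, proj_components)
        X_tr = transform(projector, train_mx)
        X_te = transform(projector, test_mx)
    else:
        X_tr, X_te = train_mx.presence, test_mx.presence
    X_tr_in = _as_model_input(np.asarray(X_tr), model_kind)
    X_te_in = _as_model_input(np.asarray(X_te), model_kind)
    y_tr_true = _labels(metadata, plan.train_ids, task)
    y_te_true = _labels(metadata, plan.test_ids, task)
    if task == "depth" and (np.isnan(y_tr_true).any() or np.isnan(y_te_true).any()):
        raise ValidationError("depth permutations require depth for all supervised genomes")
    p = X_tr_in.shape[1]
    default_param = {"RF": mc.rf_feature_grid[0],
                     "LR": 0.1 if task == "ecotype" else 0.01}[model_kind]

    rows = []
    for i in range(n_permutations):
        seed_i = plan.seed + 1000 + i
        y_shuf, frac = permute_labels(y_tr_true, seed_i)
        if task == "ecotype" and len(np.unique(y_shuf)) < 2:
            logger.warning("permutation %d skipped: single-class labels", i)
            continue
        splitter = (StratifiedKFold if task == "ecotype" else KFold)(
            n_splits=plan.cv_folds, shuffle=True, random_state=seed_i % (2 ** 31))
        split_arg = (np.zeros(len(y_shuf)), y_shuf) if task == "ecotype" else (np.zeros(len(y_shuf)),)
        fold_scores = []
        for f, (tr_idx, _va_idx) in enumerate(splitter.split(*split_arg)):
            if task == "ecotype" and len(np.unique(y_shuf[tr_idx])) < 2:
                continue
            est = _make_estimator(model_kind, task, default_param, p,
                                  mc.n_estimators, mc.l1_ratio,
                                  (seed_i * 10 + f) % (2 ** 31))
            est.fit(_index_rows(X_tr_in, tr_idx), y_shuf[tr_idx])
            fold_scores.append(_score(task, y_te_true, est.predict(X_te_in)))
        if not fold_scores:
            continue
        rows.append({"permutation": i, "seed": seed_i,
                     "fraction_correct": frac,
                     "test_score": float(np.mean(fold_scores))})
    return pd.DataFrame(rows)


def correctness_performance_correlation(records: pd.DataFrame) -> Tuple[float, float]:
    """Pearson r and Spearman rho between fraction-correct and permuted score.

    ``records`` needs columns ``fraction_correct`` and ``test_score`` with at
    least three rows and variance in both coordinates.  Spearman uses average
    ranks for ties.
    """
    x = np.asarray(records["fraction_correct"], dtype=float)
    y = np.asarray(records["test_score"], dtype=float)
    if len(x) < 3:
        raise ValueError("need at least three permutation records")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in permutation records")
    pear = float(sps.pearsonr(x, y).statistic)
    spear = float(sps.spearmanr(x, y).statistic)
    return pear, spear
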