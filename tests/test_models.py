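"""Stratification, metrics, supervised evaluation and the permutation null."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import matthews_corrcoef

from panecotype import (apply_dropout, correctness_performance_correlation, mcc,
                        permute_labels, rmse, simulate_collection,
                        stratify_by_completeness, train_evaluate)
from panecotype.config import ModelConfig
from panecotype.types import ValidationError
from conftest import tiny_simulation_config


def _meta(completeness, ecotypes=None):
    n = len(completeness)
    return pd.DataFrame({
        "genome_id": [f"g{i}" for i in range(n)],
        "ecotype": ecotypes or (["HL", "LL"] * n)[:n],
        "completeness_pct": completeness,
    })


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def test_stratify_basic():
    plan = stratify_by_completeness(_meta([80, 60, 20, 90, 50, 30]))
    assert plan.train_ids == ["g0", "g3"]
    assert plan.test_ids == ["g1", "g4", "g5"]
    assert plan.excluded_ids == ["g2"]


def test_stratify_boundaries_fall_into_test():
    plan = stratify_by_completeness(_meta([75.0, 25.0, 80.0, 76.0]))
    assert set(plan.test_ids) == {"g0", "g1"}
    assert set(plan.train_ids) == {"g2", "g3"}


def test_stratify_empty_test_rejected():
    with pytest.raises(ValidationError, match="test stratum"):
        stratify_by_completeness(_meta([100, 100, 100, 100]))


def test_stratify_unlabeled_excluded():
    meta = _meta([80, 50, 90])
    meta.loc[2, "ecotype"] = None
    plan = stratify_by_completeness(meta)
    assert "g2" in plan.excluded_ids


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_mcc_closed_forms():
    assert mcc(10, 10, 0, 0) == 1.0
    assert mcc(45, 30, 3, 2) == pytest.approx(1344 / math.sqrt(48 * 47 * 33 * 32))
    assert mcc(12, 0, 8, 0) == 0.0  # all predictions one class


def test_mcc_all_zero_rejected():
    with pytest.raises(ValueError):
        mcc(0, 0, 0, 0)


def test_mcc_symmetric_under_class_swap():
    # swapping positive/negative everywhere swaps tp<->tn and fp<->fn
    assert mcc(7, 3, 2, 5) == pytest.approx(mcc(3, 7, 5, 2))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_mcc_matches_sklearn(seed):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, 30)
    yhat = rng.integers(0, 2, 30)
    if len(np.unique(y)) < 2:
        return
    tp = int(((y == 1) & (yhat == 1)).sum()); tn = int(((y == 0) & (yhat == 0)).sum())
    fp = int(((y == 0) & (yhat == 1)).sum()); fn = int(((y == 1) & (yhat == 0)).sum())
    assert mcc(tp, tn, fp, fn) == pytest.approx(matthews_corrcoef(y, yhat), abs=1e-12)


def test_rmse_closed_forms():
    assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert rmse([0.0, 0.0], [30.0, 40.0]) == pytest.approx(math.sqrt(1250))
    truth = np.array([10.0, 20.0, 60.0])
    assert rmse(np.full(3, truth.mean()), truth) == pytest.approx(truth.std())


def test_rmse_length_mismatch():
    with pytest.raises(ValueError):
        rmse([1.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# permutation mechanics
# ---------------------------------------------------------------------------

def test_permute_preserves_multiset_and_tracks_overlap():
    labels = np.array([1, 1, 1, 0, 0])
    shuffled, frac = permute_labels(labels, seed=5)
    assert sorted(shuffled) == sorted(labels)
    assert frac == pytest.approx(np.mean(shuffled == labels))


def test_permute_identity_and_full_swap():
    labels = np.array([1, 0, 1, 0])
    # find seeds realizing the two extremes on this small vector
    fracs = {}
    for seed in range(200):
        _, frac = permute_labels(labels, seed)
        fracs[round(frac, 3)] = seed
    assert 1.0 in fracs and 0.0 in fracs


def test_permute_expected_fraction_60_40():
    """At 60:40 balance, E[fraction correct] = 0.6^2 + 0.4^2 = 0.52."""
    labels = np.array([1] * 60 + [0] * 40)
    fracs = [permute_labels(labels, seed)[1] for seed in range(400)]
    se = np.std(fracs) / np.sqrt(len(fracs))
    assert np.mean(fracs) == pytest.approx(0.52, abs=4 * se + 1e-9)


def test_correlation_exact_three_points():
    rec = pd.DataFrame({"fraction_correct": [0.4, 0.5, 0.6],
                        "test_score": [-0.2, 0.0, 0.2]})
    r, rho = correctness_performance_correlation(rec)
    assert r == pytest.approx(1.0) and rho == pytest.approx(1.0)


def test_correlation_antimonotone():
    rec = pd.DataFrame({"fraction_correct": [0.1, 0.5, 0.9],
                        "test_score": [0.5, 0.1, -0.4]})
    _, rho = correctness_performance_correlation(rec)
    assert rho == pytest.approx(-1.0)


def test_correlation_zero_variance_rejected():
    rec = pd.DataFrame({"fraction_correct": [0.5, 0.5, 0.5],
                        "test_score": [0.1, 0.2, 0.3]})
    with pytest.raises(ValueError, match="variance"):
        correctness_performance_correlation(rec)


# ---------------------------------------------------------------------------
# train/evaluate on tiny collections
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_supervised():
    cfg = tiny_simulation_config(seed=31, n_hl=(12, 10), n_ll=(8, 8))
    matrix, meta, _ = simulate_collection(cfg)
    observed = apply_dropout(matrix, meta, seed=99)
    plan = stratify_by_completeness(meta, cv_folds=3, resamples=2, seed=0)
    return matrix, observed, meta, plan


FAST = ModelConfig(n_estimators=60, tune_trees=30, rf_feature_grid=("sqrt",),
                   lr_c_grid=(1.0,), en_alpha_grid=(0.01,))


def test_rf_perfect_on_exclusive_marker(tiny_supervised):
    """With fully exclusive markers and no dropout the forest is perfect."""
    matrix, _, meta, plan = tiny_supervised
    res = train_evaluate(matrix, meta, plan, "RF", "full", "ecotype", FAST)
    assert (res.records["test_score"] == 1.0).all()
    assert len(res.records) == plan.cv_folds * plan.resamples
    assert res.importances.shape == (len(res.records), matrix.n_clusters)


def test_flipped_training_labels_give_nonpositive_mcc(tiny_supervised):
    matrix, _, meta, plan = tiny_supervised
    flipped = meta.copy()
    flipped["ecotype"] = flipped["ecotype"].map({"HL": "LL", "LL": "HL"})
    flipped["clade"] = None
    res = train_evaluate(matrix, flipped, plan, "RF", "full", "ecotype", FAST)
    # evaluate the flipped-label model against the true labels
    truth = (meta.set_index("genome_id").loc[res.predictions["genome_id"], "ecotype"]
             == "HL").to_numpy(dtype=int)
    agree = (res.predictions["prediction"].to_numpy() == truth)
    assert agree.mean() < 0.5  # anti-predictive on the true labels


def test_constant_features_score_zero(tiny_supervised):
    matrix, _, meta, plan = tiny_supervised
    from panecotype.types import GeneClusterMatrix
    const = GeneClusterMatrix(matrix.genome_ids, ["c0", "c1"],
                              np.ones((matrix.n_genomes, 2), dtype=np.uint8))
    res = train_evaluate(const, meta, plan, "RF", "full", "ecotype", FAST)
    assert (res.records["test_score"] == 0.0).all()


@pytest.mark.parametrize("space", ["reduced", "projected"])
def test_feature_spaces_run(tiny_supervised, space):
    matrix, observed, meta, plan = tiny_supervised
    res = train_evaluate(observed, meta, plan, "RF", space, "ecotype", FAST,
                         reduction_cutoff=0.05, n_components=5)
    assert res.records["test_score"].between(-1, 1).all()
    if space == "projected":
        assert res.importance_ids == [f"PC{k+1}" for k in range(5)]


def test_lr_classification_and_importances(tiny_supervised):
    matrix, _, meta, plan = tiny_supervised
    res = train_evaluate(matrix, meta, plan, "LR", "full", "ecotype", FAST)
    assert res.records["test_score"].min() > 0.8
    top = np.asarray(res.importance_ids)[np.argsort(-res.importances[0])][:6]
    assert {"marker_hl", "marker_ll"} <= set(top)


def test_depth_regression_runs(tiny_supervised):
    matrix, _, meta, plan = tiny_supervised
    res = train_evaluate(matrix, meta, plan, "RF", "full", "depth", FAST)
    assert (res.records["test_score"] >= 0).all()
    # predicting with genotype beats predicting the grand mean
    truth = res.predictions["truth"]
    assert res.records["test_score"].mean() < truth.std() * 1.05
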