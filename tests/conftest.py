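"""Shared fixtures.

Paper-scale objects (the default synthetic collection and the model runs on
it) are session-scoped because they are expensive; unit tests use the tiny
collection builders instead.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from panecotype import (
    apply_dropout,
    run_label_permutations,
    simulate_collection,
    stratify_by_completeness,
    train_evaluate,
)
from panecotype.config import (
    ANIModel,
    BlockSpec,
    CladeSpec,
    CompletenessPlan,
    DepthModel,
    MarkerSpec,
    MetricModel,
    SimulationConfig,
    TransitionalPlan,
    default_pipeline_config,
)

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


def tiny_simulation_config(seed: int = 0, n_hl: tuple = (6, 6), n_ll: tuple = (4, 4),
                           marker_plan=None, block_plan=None,
                           transitional: int = 0) -> SimulationConfig:
    """A two-clade collection small enough for exhaustive unit checks."""
    if marker_plan is None:
        marker_plan = [MarkerSpec("marker_hl", 1.00, 0.00),
                       MarkerSpec("marker_ll", 0.00, 1.00)]
    if block_plan is None:
        block_plan = [
            BlockSpec("ultra_rare", "ultra_rare", 30, carrier_choices=(1, 2),
                      choice_weights=(0.5, 0.5)),
            BlockSpec("hl_common", "ecotype", 10, ecotype="HL", prev_lo=0.5, prev_hi=0.9),
            BlockSpec("ll_common", "ecotype", 10, ecotype="LL", prev_lo=0.5, prev_hi=0.9),
            BlockSpec("core", "core", 8, prev_lo=0.95, prev_hi=1.0),
        ]
    total = sum(b.n_clusters for b in block_plan) + len(marker_plan)
    n_hl_g, n_ll_g = sum(n_hl), sum(n_ll)
    cfg = SimulationConfig(
        n_genomes=n_hl_g + n_ll_g,
        hl_fraction=n_hl_g / (n_hl_g + n_ll_g),
        total_clusters=total,
        rare_cluster_count=None,
        rare_prevalence_max=0.15,
        clade_plan=[CladeSpec("HLI", "HL", *n_hl), CladeSpec("LLI", "LL", *n_ll)],
        marker_plan=marker_plan,
        homolog_pairs=[],
        block_plan=block_plan,
        completeness_plan=CompletenessPlan(),
        transitional_plan=TransitionalPlan(n_genomes=transitional,
                                           source_clade="HLI", effective_clade="LLI"),
        dropout_mode="none",
        depth_model=DepthModel(clade_means_m={"HLI": 30.0, "LLI": 110.0}, sd_m=20.0),
        depth_range_quota=(0, 0),
        n_missing_depth=0,
        ani_model=ANIModel(),
        metric_model=MetricModel(
            means={"HLI": (1.7e6, 31.0, 0.9, 0.25), "LLI": (2.0e6, 36.0, 0.88, 0.3)},
            sds={"HLI": (5e4, 0.5, 0.01, 0.02), "LLI": (5e4, 0.5, 0.01, 0.02)},
        ),
        batch_weights={"A": 1.0},
        reduced_feature_target=0,
        seed=seed,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# paper-scale session fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def pipeline_cfg():
    return default_pipeline_config(seed=1)


@pytest.fixture(scope="session")
def default_collection(pipeline_cfg):
    """The full-scale default synthetic collection (intrinsic matrix)."""
    return simulate_collection(pipeline_cfg.simulation)


@pytest.fixture(scope="session")
def observed_matrix(pipeline_cfg, default_collection):
    matrix, meta, _ = default_collection
    return apply_dropout(matrix, meta, seed=pipeline_cfg.simulation.seed + 5)


@pytest.fixture(scope="session")
def split_plan(pipeline_cfg, default_collection):
    _, meta, _ = default_collection
    return stratify_by_completeness(
        meta, pipeline_cfg.train_threshold, pipeline_cfg.completeness_floor,
        pipeline_cfg.cv_folds, pipeline_cfg.resamples, pipeline_cfg.seed)


@pytest.fixture(scope="session")
def rf_full_result(pipeline_cfg, default_collection, observed_matrix, split_plan):
    """RF ecotype classification on the full space: 10 resamples x 5 folds."""
    _, meta, _ = default_collection
    return train_evaluate(observed_matrix, meta, split_plan, "RF", "full",
                          "ecotype", pipeline_cfg.model)


@pytest.fixture(scope="session")
def lr_full_result(pipeline_cfg, default_collection, observed_matrix, split_plan):
    _, meta, _ = default_collection
    return train_evaluate(observed_matrix, meta, split_plan, "LR", "full",
                          "ecotype", pipeline_cfg.model)


@pytest.fixture(scope="session")
def permutation_records(pipeline_cfg, default_collection, observed_matrix, split_plan):
    _, meta, _ = default_collection
    return run_label_permutations(observed_matrix, meta, split_plan,
                                  pipeline_cfg.n_permutations, "LR", "ecotype",
                                  pipeline_cfg.model)
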