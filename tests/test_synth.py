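"""Generator quota exactness, determinism, dropout coupling, depth and ANI."""

import numpy as np
import pandas as pd
import pytest

from panecotype import apply_dropout, simulate_ani, simulate_collection, simulate_depth
from panecotype.config import BlockSpec, ConfigurationError, MarkerSpec
from conftest import tiny_simulation_config


def test_empty_collection_rejected():
    cfg = tiny_simulation_config()
    cfg.n_genomes = 0
    cfg.clade_plan = []
    with pytest.raises(ConfigurationError):
        simulate_collection(cfg)


def test_determinism_bitwise():
    cfg = tiny_simulation_config(seed=7)
    a = simulate_collection(cfg)
    b = simulate_collection(tiny_simulation_config(seed=7))
    assert np.array_equal(a[0].presence, b[0].presence)
    pd.testing.assert_frame_equal(a[1], b[1])
    pd.testing.assert_frame_equal(a[2].records, b[2].records)
    c = simulate_collection(tiny_simulation_config(seed=8))
    assert not np.array_equal(a[0].presence, c[0].presence)


def test_exclusive_marker_column_is_ecotype_indicator():
    """A marker at HL prevalence 1.0 / LL 0.0 marks exactly the HL genomes."""
    cfg = tiny_simulation_config(
        n_hl=(1, 0), n_ll=(1, 0),
        marker_plan=[MarkerSpec("m", 1.0, 0.0)],
        block_plan=[BlockSpec("ultra_rare", "ultra_rare", 2, carrier_choices=(1,),
                              choice_weights=(1.0,))],
    )
    matrix, meta, _ = simulate_collection(cfg)
    col = matrix.presence[:, matrix.cluster_ids.index("m")]
    hl = (meta["ecotype"] == "HL").to_numpy().astype(np.uint8)
    assert np.array_equal(col, hl)


def test_marker_quotas_exact_over_seeds():
    for seed in (0, 1, 2):
        cfg = tiny_simulation_config(
            seed=seed, n_hl=(10, 5), n_ll=(10, 5),
            marker_plan=[MarkerSpec("m", 0.8, 0.1)])
        matrix, meta, _ = simulate_collection(cfg)
        comp = meta["completeness_pct"].to_numpy()
        train = comp > 75
        hl = (meta["ecotype"] == "HL").to_numpy()
        col = matrix.presence[:, matrix.cluster_ids.index("m")]
        assert col[train & hl].sum() == 8      # 0.8 * 10
        assert col[train & ~hl].sum() == 1     # 0.1 * 10


def test_block_quota_counts_exact():
    cfg = tiny_simulation_config(seed=3)
    matrix, meta, _ = simulate_collection(cfg)
    counts = matrix.presence.sum(axis=0)
    ids = np.asarray(matrix.cluster_ids)
    rare = counts[np.char.startswith(ids.astype(str), "ultra_rare")]
    assert set(rare) <= {1, 2}
    assert (rare == 1).sum() == 15 and (rare == 2).sum() == 15


def test_grouped_placement_counts_exact_and_overlapping():
    blocks = [
        BlockSpec("grp", "ecotype", 9, ecotype="HL", prev_lo=0.5, prev_hi=0.5,
                  group_size=3, group_overlap=0.9),
        BlockSpec("ultra_rare", "ultra_rare", 5, carrier_choices=(1,), choice_weights=(1.0,)),
    ]
    cfg = tiny_simulation_config(seed=4, n_hl=(10, 10), n_ll=(5, 5),
                                 marker_plan=[MarkerSpec("m", 1.0, 0.0)],
                                 block_plan=blocks)
    matrix, meta, _ = simulate_collection(cfg)
    cols = [j for j, c in enumerate(matrix.cluster_ids) if str(c).startswith("grp")]
    sub = matrix.presence[:, cols]
    assert (sub.sum(axis=0) == 10).all()  # 0.5 of the 20 HL genomes, exact
    # members of a group share most carriers
    a, b = sub[:, 0].astype(bool), sub[:, 1].astype(bool)
    assert (a & b).sum() >= 8


def test_transitional_genomes_receive_opposite_profile():
    cfg = tiny_simulation_config(seed=5, n_hl=(6, 6), n_ll=(4, 4), transitional=2)
    matrix, meta, _ = simulate_collection(cfg)
    trans = meta["transitional"].to_numpy()
    assert trans.sum() == 2
    assert (meta.loc[trans, "ecotype"] == "HL").all()  # still labeled HL
    ids = np.asarray(matrix.cluster_ids).astype(str)
    ll_cols = np.char.startswith(ids, "ll_common") | (ids == "marker_ll")
    hl_cols = np.char.startswith(ids, "hl_common") | (ids == "marker_hl")
    ll_load = matrix.presence[:, ll_cols].mean(axis=1)
    hl_load = matrix.presence[:, hl_cols].mean(axis=1)
    assert (ll_load[trans] > hl_load[trans]).all()


# ---------------------------------------------------------------------------
# dropout
# ---------------------------------------------------------------------------

@pytest.fixture()
def tiny_collection():
    cfg = tiny_simulation_config(seed=11, n_hl=(10, 10), n_ll=(6, 6))
    return simulate_collection(cfg)


def test_dropout_full_completeness_is_identity(tiny_collection):
    matrix, meta, _ = tiny_collection
    meta = meta.copy()
    meta["completeness_pct"] = 100.0
    out = apply_dropout(matrix, meta, seed=1)
    assert np.array_equal(out.presence, matrix.presence)


def test_dropout_monotone_nesting(tiny_collection):
    """Lowering one genome's completeness only removes genes (coupled draws)."""
    matrix, meta, _ = tiny_collection
    hi = meta.copy(); hi["completeness_pct"] = 80.0
    lo = meta.copy(); lo["completeness_pct"] = 80.0
    lo.loc[lo.index[0], "completeness_pct"] = 50.0
    out_hi = apply_dropout(matrix, hi, seed=3)
    out_lo = apply_dropout(matrix, lo, seed=3)
    row_hi, row_lo = out_hi.presence[0], out_lo.presence[0]
    assert not (row_lo & ~row_hi).any()          # subset
    assert np.array_equal(out_hi.presence[1:], out_lo.presence[1:])  # untouched rows equal


def test_dropout_never_creates_presence(tiny_collection):
    matrix, meta, _ = tiny_collection
    out = apply_dropout(matrix, meta, seed=5)
    assert not (out.presence & ~matrix.presence).any()


def test_dropout_survivor_expectation():
    """At low completeness the survivor count matches the binomial mean."""
    n_present = 10_000
    eps = 5.0  # completeness %
    from panecotype.types import GeneClusterMatrix
    matrix = GeneClusterMatrix(["g0"], [f"c{i}" for i in range(n_present)],
                               np.ones((1, n_present), dtype=np.uint8))
    meta = pd.DataFrame({"genome_id": ["g0"], "ecotype": ["HL"],
                         "completeness_pct": [eps]})
    survivors = [apply_dropout(matrix, meta, seed=s).presence.sum() for s in range(8)]
    expect = eps / 100 * n_present
    sd = np.sqrt(n_present * eps / 100 * (1 - eps / 100))
    assert abs(np.mean(survivors) - expect) < 4 * sd / np.sqrt(len(survivors))


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------

def test_depth_zero_noise_hits_clade_means():
    cfg = tiny_simulation_config(seed=2)
    cfg.depth_model.sd_m = 0.0
    matrix, meta, _ = simulate_collection(cfg)
    want = meta["clade"].map(cfg.depth_model.clade_means_m)
    assert np.allclose(meta["depth_m"], want)


def test_depth_truncated_at_zero():
    cfg = tiny_simulation_config(seed=9)
    cfg.depth_model = type(cfg.depth_model)(clade_means_m={"HLI": 30.0, "LLI": 35.0}, sd_m=40.0)
    _, meta, _ = simulate_collection(cfg)
    assert (meta["depth_m"].dropna() >= 0).all()


def test_depth_missing_quota():
    cfg = tiny_simulation_config(seed=2, n_hl=(10, 10), n_ll=(5, 5))
    cfg.n_missing_depth = 4
    _, meta, _ = simulate_collection(cfg)
    assert meta["depth_m"].isna().sum() == 4


def test_default_depth_mostly_shallow(default_collection):
    """Nearly all isolation depths fall in the photic 0-150 m band."""
    _, meta, _ = default_collection
    depth = meta["depth_m"].dropna()
    assert ((depth >= 0) & (depth <= 150)).mean() >= 0.90
    hl_mean = meta.loc[meta.ecotype == "HL", "depth_m"].mean()
    ll_mean = meta.loc[meta.ecotype == "LL", "depth_m"].mean()
    assert hl_mean < ll_mean


# ---------------------------------------------------------------------------
# ANI
# ---------------------------------------------------------------------------

def test_ani_zero_noise_exact_medians():
    cfg = tiny_simulation_config(seed=6)
    cfg.ani_model.noise_sd_pct = 0.0
    matrix, meta, ani = simulate_collection(cfg)
    clade = meta.set_index("genome_id")["clade"]
    rep = ani.reported()
    same = rep["query"].map(clade).to_numpy() == rep["reference"].map(clade).to_numpy()
    assert np.allclose(rep.loc[same, "ani_pct"], cfg.ani_model.within_median_pct)
    assert np.allclose(rep.loc[~same, "ani_pct"], cfg.ani_model.between_median_pct)


def test_ani_censoring_floor():
    cfg = tiny_simulation_config(seed=6, n_hl=(10, 10), n_ll=(10, 10))
    cfg.ani_model.noise_sd_pct = 2.0
    _, _, ani = simulate_collection(cfg)
    rep = ani.reported()
    assert (rep["ani_pct"] >= cfg.ani_model.reporting_floor_pct).all()
    assert ani.records["ani_pct"].isna().any()  # some pairs censored


def test_ani_single_genome_empty():
    cfg = tiny_simulation_config(seed=1, n_hl=(1, 0), n_ll=(0, 0),
                                 marker_plan=[MarkerSpec("m", 1.0, 0.0)],
                                 block_plan=[BlockSpec("ultra_rare", "ultra_rare", 2,
                                                       carrier_choices=(1,),
                                                       choice_weights=(1.0,))])
    cfg.hl_fraction = 1.0
    cfg.clade_plan = [c for c in cfg.clade_plan if c.ecotype == "HL"]
    cfg.validate()
    _, meta, ani = simulate_collection(cfg)
    assert len(ani) == 0


def test_ani_symmetric_both_directions():
    cfg = tiny_simulation_config(seed=12)
    _, _, ani = simulate_collection(cfg)
    rec = ani.records.set_index(["query", "reference"])["ani_pct"]
    fwd = rec.loc[("G0000", "G0001")]
    rev = rec.loc[("G0001", "G0000")]
    assert (fwd == rev) or (np.isnan(fwd) and np.isnan(rev))
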