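"""Exact tests, BH correction, ANI comparison and rank-based metric tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from panecotype import bh_adjust, fisher_per_cluster, metric_tests, simulate_collection
from panecotype.ecostats import ani_within_between, _dunn_pairwise
from panecotype.types import ANITable, GeneClusterMatrix, ValidationError
from conftest import tiny_simulation_config


# ---------------------------------------------------------------------------
# Fisher exact: brute-force hypergeometric oracle
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(a, b, c, d):
    """Sum hypergeometric probabilities <= the observed table's probability."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):  # table [[x, row1-x], [col1-x, ...]] with fixed margins
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))

    p_obs = prob(a)
    lo, hi = max(0, row1 - (n - col1)), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def _matrix_for_counts(tables):
    """Build a matrix + metadata realizing the (a, b) presence counts.

    All tables share margins (n_hl, n_ll)."""
    n_hl = tables[0][0] + tables[0][2]
    n_ll = tables[0][1] + tables[0][3]
    cols = []
    for a, b, c, d in tables:
        col = np.zeros(n_hl + n_ll, dtype=np.uint8)
        col[:a] = 1
        col[n_hl:n_hl + b] = 1
        cols.append(col)
    X = np.stack(cols, axis=1)
    ids = [f"g{i}" for i in range(n_hl + n_ll)]
    meta = pd.DataFrame({"genome_id": ids,
                         "ecotype": ["HL"] * n_hl + ["LL"] * n_ll,
                         "completeness_pct": 100.0})
    return GeneClusterMatrix(ids, [f"c{j}" for j in range(len(tables))], X), meta


def test_fisher_matches_enumeration_oracle_small_margins():
    """Exhaustive check against the hypergeometric oracle, margins <= 12."""
    for n_hl, n_ll in [(4, 3), (6, 6), (7, 5)]:
        tables = [(a, b, n_hl - a, n_ll - b)
                  for a in range(n_hl + 1) for b in range(n_ll + 1)
                  if a + b > 0]
        matrix, meta = _matrix_for_counts(tables)
        out = fisher_per_cluster(matrix, meta)
        for row, (a, b, c, d) in zip(out.itertuples(), tables):
            assert row.p_value == pytest.approx(fisher_two_sided_oracle(a, b, c, d),
                                                rel=1e-9), (a, b, c, d)


def test_fisher_mutually_exclusive_table():
    matrix, meta = _matrix_for_counts([(10, 0, 0, 10)])
    out = fisher_per_cluster(matrix, meta)
    assert out.loc[0, "infinite_or"]
    assert np.isinf(out.loc[0, "odds_ratio"])
    assert out.loc[0, "p_value"] == pytest.approx(2 / math.comb(20, 10))


def test_fisher_balanced_table():
    matrix, meta = _matrix_for_counts([(5, 5, 5, 5)])
    out = fisher_per_cluster(matrix, meta)
    assert out.loc[0, "odds_ratio"] == pytest.approx(1.0)
    assert out.loc[0, "p_value"] == pytest.approx(1.0)


def test_fisher_skips_absent_clusters(caplog):
    matrix, meta = _matrix_for_counts([(3, 2, 3, 4), (0, 0, 6, 6)])
    with caplog.at_level("INFO"):
        out = fisher_per_cluster(matrix, meta)
    assert len(out) == 1 and out.loc[0, "cluster_id"] == "c0"


def test_fisher_null_calibration():
    """On label-permuted data almost nothing clears BH at 0.05."""
    cfg = tiny_simulation_config(seed=17, n_hl=(15, 15), n_ll=(10, 10))
    matrix, meta, _ = simulate_collection(cfg)
    rng = np.random.default_rng(0)
    rates = []
    for _ in range(5):
        shuffled = meta.copy()
        shuffled["ecotype"] = rng.permutation(shuffled["ecotype"].to_numpy())
        shuffled["clade"] = None
        out = fisher_per_cluster(matrix, shuffled)
        rates.append((out["p_adjusted"] < 0.05).mean())
    assert np.mean(rates) < 0.01


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

def test_bh_step_up_examples():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)


def test_bh_rejects_out_of_range():
    for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan]):
        with pytest.raises(ValueError):
            bh_adjust(bad)


def test_bh_matches_hand_step_up():
    rng = np.random.default_rng(3)
    for _ in range(20):
        p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 15))
        got = bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        hand = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * m / rank)
            hand[idx] = running
        assert np.allclose(got, hand)
        assert (got >= p - 1e-12).all()


# ---------------------------------------------------------------------------
# ANI comparison
# ---------------------------------------------------------------------------

def _ani(rows):
    return ANITable(pd.DataFrame(rows, columns=["query", "reference", "ani_pct",
                                                "mapped", "total"]))


def _meta(clades):
    return pd.DataFrame({"genome_id": list(clades),
                         "ecotype": ["HL"] * len(clades),
                         "clade": [f"HL{c}" for c in clades.values()],
                         "completeness_pct": 100.0})


def test_ani_within_between_medians():
    meta = _meta({"g1": "A", "g2": "A", "g3": "B"})
    ani = _ani([("g1", "g2", 92.0, 1, 1), ("g1", "g3", 80.0, 1, 1),
                ("g2", "g3", 79.0, 1, 1)])
    cmp = ani_within_between(ani, meta)
    assert cmp.within_median_pct == pytest.approx(92.0)
    assert cmp.between_median_pct == pytest.approx(79.5)


def test_ani_all_equal_p_one():
    meta = _meta({"g1": "A", "g2": "A", "g3": "B", "g4": "B"})
    ani = _ani([("g1", "g2", 85.0, 1, 1), ("g3", "g4", 85.0, 1, 1),
                ("g1", "g3", 85.0, 1, 1), ("g2", "g4", 85.0, 1, 1)])
    assert ani_within_between(ani, meta).p_value == pytest.approx(1.0)


def test_ani_empty_stratum_rejected():
    meta = _meta({"g1": "A", "g2": "A"})
    ani = _ani([("g1", "g2", 92.0, 1, 1)])
    with pytest.raises(ValidationError):
        ani_within_between(ani, meta)


def test_ani_symmetric_duplicates_counted_once():
    meta = _meta({"g1": "A", "g2": "A", "g3": "B"})
    ani = _ani([("g1", "g2", 92.0, 1, 1), ("g2", "g1", 92.0, 1, 1),
                ("g1", "g3", 80.0, 1, 1), ("g3", "g1", 80.0, 1, 1)])
    cmp = ani_within_between(ani, meta)
    assert len(cmp.within_values) == 1 and len(cmp.between_values) == 1


# ---------------------------------------------------------------------------
# metric tests
# ---------------------------------------------------------------------------

def _metric_meta(groups, metric="gc_pct"):
    rows = []
    for clade, values in groups.items():
        eco = "HL" if clade.startswith("HL") else "LL"
        for i, v in enumerate(values):
            rows.append({"genome_id": f"{clade}_{i}", "ecotype": eco,
                         "clade": clade, "completeness_pct": 100.0, metric: v})
    return pd.DataFrame(rows)


def test_identical_groups_p_one():
    meta = _metric_meta({"HLI": [5, 5, 5], "LLI": [5, 5, 5]})
    rep = metric_tests(meta, metrics=["gc_pct"])
    assert rep.ecotype_tests.loc[0, "p_value"] == pytest.approx(1.0)


def test_kruskal_h_for_ordered_groups():
    """Three non-overlapping ordered groups of 3: H = 12/(N(N+1)) * sum n(rbar-r)^2 = 7.2."""
    meta = _metric_meta({"HLI": [1, 2, 3], "HLII": [4, 5, 6], "LLI": [7, 8, 9]})
    rep = metric_tests(meta, metrics=["gc_pct"])
    assert rep.clade_tests.loc[0, "H"] == pytest.approx(7.2)


def test_small_clades_flagged_untested():
    meta = _metric_meta({"HLI": [1, 2, 3, 4], "LLI": [5, 6, 7], "LLIV": [9]})
    rep = metric_tests(meta, metrics=["gc_pct"], min_group=3)
    assert rep.untested_groups["gc_pct"] == ["LLIV"]
    assert "LLIV" not in rep.clade_tests.loc[0, "clades"]
    pairs = set(map(tuple, rep.dunn_tests[["clade_a", "clade_b"]].to_numpy()))
    assert ("HLI", "LLI") in pairs and not any("LLIV" in p for p in pairs)


def test_dunn_z_matches_direct_arithmetic():
    """Hand-check the Dunn z statistic on a tiny no-tie example."""
    groups = {"HLI": np.array([1.0, 2.0, 3.0]), "LLI": np.array([4.0, 5.0, 6.0])}
    dunn = _dunn_pairwise(list(groups.values()), list(groups))
    # pooled ranks: 1..6, mean ranks 2 and 5; var unit = 6*7/12 = 3.5
    z_expect = (2 - 5) / math.sqrt(3.5 * (1 / 3 + 1 / 3))
    assert dunn.loc[0, "z"] == pytest.approx(z_expect)
    assert dunn.loc[0, "p_value"] == pytest.approx(2 * sps.norm.sf(abs(z_expect)))


def test_metric_missing_everywhere_skipped(caplog):
    meta = _metric_meta({"HLI": [1, 2, 3], "LLI": [4, 5, 6]})
    with caplog.at_level("WARNING"):
        rep = metric_tests(meta, metrics=["coding_density"])
    assert len(rep.ecotype_tests) == 0


def test_dunn_bh_within_metric_family():
    meta = _metric_meta({"HLI": [1, 2, 3], "HLII": [2, 3, 4], "LLI": [8, 9, 10]})
    rep = metric_tests(meta, metrics=["gc_pct"])
    d = rep.dunn_tests
    assert np.allclose(d["p_adjusted"], bh_adjust(d["p_value"].to_numpy()))
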