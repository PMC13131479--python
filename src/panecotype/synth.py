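"""Synthetic fragmented-pangenome generator.

Generates genome collections whose statistical structure mirrors a large
marine-cyanobacterial isolate collection: a huge ultra-rare accessory tail,
clade-specific gene blocks, ecotype-exclusive and ecotype-biased gene
clusters, a small conserved core, planted marker homologs with exact
training-stratum prevalences, completeness-stratified genomes with
completeness-proportional gene dropout, clade-structured depths of isolation
and genome metrics, and a censored pairwise ANI table.

Quota discipline: every block assigns *deterministic carrier counts* and
randomizes only which genomes carry each cluster, so collection-level counts
(total clusters, rare clusters, marker prevalences, class balance) are exact
on every seed rather than merely in expectation.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig
from .types import ANITable, GeneClusterMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "simulate_collection",
    "apply_dropout",
    "simulate_depth",
    "simulate_ani",
]


def _iround(x: float) -> int:
    """Round half up (avoids banker's rounding surprises in quota arithmetic)."""
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

def _build_genomes(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-genome frame with clade, ecotype, stratum, completeness and batch.

    Adds two internal columns: ``stratum`` ("train"/"test") and
    ``effective_clade`` — the clade whose gene profile the genome receives.
    Transitional genomes keep their true (labeled) clade/ecotype but receive
    the profile of a clade from the opposite ecotype.
    """
    rows = []
    for clade in cfg.clade_plan:
        for stratum, count in (("train", clade.n_train), ("test", clade.n_test)):
            for _ in range(count):
                rows.append({
                    "clade": clade.label,
                    "ecotype": clade.ecotype,
                    "stratum": stratum,
                })
    df = pd.DataFrame(rows)
    df["genome_id"] = [f"G{i:04d}" for i in range(len(df))]

    # completeness quotas: evenly spaced per stratum, shuffled over genomes
    lo, hi = cfg.completeness_plan.train_range
    train_idx = np.flatnonzero((df["stratum"] == "train").to_numpy())
    vals = np.linspace(lo, hi, len(train_idx))
    df.loc[train_idx, "completeness_pct"] = rng.permutation(vals)
    lo, hi = cfg.completeness_plan.test_range
    test_idx = np.flatnonzero((df["stratum"] == "test").to_numpy())
    vals = np.linspace(lo, hi, len(test_idx)) if len(test_idx) else np.array([])
    df.loc[test_idx, "completeness_pct"] = rng.permutation(vals)

    # transitional genomes: HL test genomes with an LL gene profile
    tp = cfg.transitional_plan
    df["effective_clade"] = df["clade"]
    df["transitional"] = False
    if tp.n_genomes > 0:
        pool = np.flatnonzero(
            ((df["clade"] == tp.source_clade) & (df["stratum"] == "test")).to_numpy()
        )
        if len(pool) < tp.n_genomes:
            raise ConfigurationError(
                f"transitional_plan: clade {tp.source_clade} test stratum has "
                f"{len(pool)} genomes, need {tp.n_genomes}"
            )
        chosen = rng.choice(pool, size=tp.n_genomes, replace=False)
        df.loc[chosen, "effective_clade"] = tp.effective_clade
        df.loc[chosen, "transitional"] = True

    eco_by_clade = {c.label: c.ecotype for c in cfg.clade_plan}
    df["effective_ecotype"] = df["effective_clade"].map(eco_by_clade)

    # subclade assignment: finer population structure within each clade,
    # balanced random partition; transitional genomes draw a subclade of
    # their effective clade
    n_sub = {c.label: max(1, c.n_subclades) for c in cfg.clade_plan}
    df["subclade"] = ""
    for label in n_sub:
        idx = np.flatnonzero((df["effective_clade"] == label).to_numpy())
        order = rng.permutation(idx)
        for k, chunk in enumerate(np.array_split(order, n_sub[label])):
            df.loc[chunk, "subclade"] = f"{label}.{k + 1}"

    batches = list(cfg.batch_weights)
    weights = np.array([cfg.batch_weights[b] for b in batches], dtype=float)
    df["batch"] = rng.choice(batches, size=len(df), p=weights / weights.sum())
    return df


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

def _choose_k_per_row(rng: np.random.Generator, pool: np.ndarray, ks: np.ndarray,
                      X: np.ndarray, col_start: int) -> None:
    """For cluster i, mark ``ks[i]`` random members of ``pool`` present.

    Uses a random-key ranking so the carrier subset is uniform; the count is
    exact per cluster.
    """
    m, g = len(ks), len(pool)
    if m == 0:
        return
    keys = rng.random((m, g))
    ranks = np.argsort(np.argsort(keys, axis=1), axis=1)
    mask = ranks < ks[:, None]
    X[np.ix_(pool, range(col_start, col_start + m))] = mask.T.astype(np.uint8)


def _choose_k_grouped(rng: np.random.Generator, pool: np.ndarray, ks: np.ndarray,
                      X: np.ndarray, col_start: int, group_size: int,
                      overlap: float) -> None:
    """Grouped carrier placement: clusters within a group share most carriers.

    Emulates linked gene cassettes (operons, genomic islands) whose members
    co-occur.  Each group draws a base carrier set; every member keeps an
    ``overlap`` fraction of it and swaps the rest for random non-members, so
    per-cluster carrier counts stay exact.
    """
    m, g = len(ks), len(pool)
    col = col_start
    i = 0
    while i < m:
        members = range(i, min(i + group_size, m))
        k_base = int(ks[i])
        base = rng.choice(g, size=k_base, replace=False)
        base_set = set(base.tolist())
        others = np.array([x for x in range(g) if x not in base_set])
        for j in members:
            k = int(ks[j])
            keep = min(k, _iround(overlap * k), k_base)
            kept = rng.choice(base, size=keep, replace=False) if keep else np.array([], dtype=int)
            extra_n = k - keep
            if extra_n > 0:
                extra = rng.choice(others, size=min(extra_n, len(others)), replace=False)
                carriers = np.concatenate([kept, extra])
            else:
                carriers = kept
            X[pool[carriers], col + (j - i)] = 1
        col += len(range(i, min(i + group_size, m)))
        i += group_size


def _place_ultra_rare(rng, block, n_genomes, X, col_start) -> None:
    choices = block.carrier_choices or (1, 2)
    weights = block.choice_weights or tuple(1 / len(choices) for _ in choices)
    counts = [_iround(w * block.n_clusters) for w in weights[:-1]]
    counts.append(block.n_clusters - sum(counts))
    col = col_start
    for c, m in zip(choices, counts):
        if m <= 0:
            continue
        draws = rng.integers(0, n_genomes, size=(m, c))
        if c > 1:  # enforce distinct carriers per cluster
            bad = np.flatnonzero([len(set(r)) < c for r in draws])
            for i in bad:
                draws[i] = rng.choice(n_genomes, size=c, replace=False)
        cols = np.repeat(np.arange(col, col + m), c)
        X[draws.ravel(), cols] = 1
        col += m


def _marker_counts(prev: float, n_train: int, n_test: int) -> Tuple[int, int]:
    return _iround(prev * n_train), _iround(prev * n_test)


def simulate_collection(cfg: SimulationConfig):
    """Generate ``(GeneClusterMatrix, metadata frame, ANITable)``.

    The returned matrix is the *intrinsic* (complete-genome) presence/absence
    matrix; completeness-driven gene loss is applied separately with
    :func:`apply_dropout` so quota statements about the collection stay exact.
    Fully reproducible from ``cfg.seed``.
    """
    cfg.validate()
    rng_genomes = np.random.default_rng([cfg.seed, 0])
    rng_matrix = np.random.default_rng([cfg.seed, 1])

    meta = _build_genomes(cfg, rng_genomes)
    n = len(meta)

    pools = {
        ("HL", "train"): np.flatnonzero(((meta["effective_ecotype"] == "HL") & (meta["stratum"] == "train")).to_numpy()),
        ("HL", "test"): np.flatnonzero(((meta["effective_ecotype"] == "HL") & (meta["stratum"] == "test")).to_numpy()),
        ("LL", "train"): np.flatnonzero(((meta["effective_ecotype"] == "LL") & (meta["stratum"] == "train")).to_numpy()),
        ("LL", "test"): np.flatnonzero(((meta["effective_ecotype"] == "LL") & (meta["stratum"] == "test")).to_numpy()),
    }
    clade_pools = {
        c.label: np.flatnonzero((meta["effective_clade"] == c.label).to_numpy())
        for c in cfg.clade_plan
    }
    subclade_pools = {
        c.label: [np.flatnonzero((meta["subclade"] == f"{c.label}.{k + 1}").to_numpy())
                  for k in range(max(1, c.n_subclades))]
        for c in cfg.clade_plan
    }

    total = cfg.total_clusters
    X = np.zeros((n, total), dtype=np.uint8)
    cluster_ids: list = []
    col = 0

    # --- planted markers: exact per-stratum quotas -----------------------
    for m in cfg.marker_plan:
        for eco, prev in (("HL", m.hl_prevalence), ("LL", m.ll_prevalence)):
            tr_pool, te_pool = pools[(eco, "train")], pools[(eco, "test")]
            k_tr, k_te = _marker_counts(prev, len(tr_pool), len(te_pool))
            for pool, k in ((tr_pool, k_tr), (te_pool, k_te)):
                if k > len(pool):
                    raise ConfigurationError(
                        f"marker_plan: {m.cluster_id} quota {k} exceeds pool of {len(pool)}"
                    )
                if k > 0:
                    X[rng_matrix.choice(pool, size=k, replace=False), col] = 1
        cluster_ids.append(m.cluster_id)
        col += 1

    # --- quota blocks ----------------------------------------------------
    for block in cfg.block_plan:
        m = block.n_clusters
        if block.kind == "ultra_rare":
            _place_ultra_rare(rng_matrix, block, n, X, col)
        elif block.kind == "clade":
            pool = clade_pools[block.clade]
            k = min(block.carrier_count, len(pool))
            if block.group_size and block.group_size > 1:
                _choose_k_grouped(rng_matrix, pool, np.full(m, k), X, col,
                                  block.group_size, block.group_overlap or 0.85)
            else:
                _choose_k_per_row(rng_matrix, pool, np.full(m, k), X, col)
        elif block.kind == "subclade":
            sub_pools = subclade_pools[block.clade]
            prevs = rng_matrix.uniform(block.prev_lo, block.prev_hi, size=m)
            for i in range(m):  # cycle clusters over the clade's subclades
                pool = sub_pools[i % len(sub_pools)]
                k = min(_iround(prevs[i] * len(pool)), len(pool))
                if k > 0:
                    X[rng_matrix.choice(pool, size=k, replace=False), col + i] = 1
        elif block.kind == "ecotype":
            pool = np.concatenate([pools[(block.ecotype, "train")], pools[(block.ecotype, "test")]])
            prevs = rng_matrix.uniform(block.prev_lo, block.prev_hi, size=m)
            ks = np.array([_iround(p * len(pool)) for p in prevs])
            if block.group_size and block.group_size > 1:
                _choose_k_grouped(rng_matrix, pool, ks, X, col,
                                  block.group_size, block.group_overlap or 0.85)
            else:
                _choose_k_per_row(rng_matrix, pool, ks, X, col)
        elif block.kind == "shared":
            major = block.ecotype
            minor = "LL" if major == "HL" else "HL"
            major_pool = np.concatenate([pools[(major, "train")], pools[(major, "test")]])
            minor_pool = np.concatenate([pools[(minor, "train")], pools[(minor, "test")]])
            prevs = rng_matrix.uniform(block.prev_lo, block.prev_hi, size=m)
            major_ks = np.array([_iround(p * len(major_pool)) for p in prevs])
            minor_prevs = np.clip(prevs - block.minor_offset, 0.0, 1.0)
            minor_ks = np.array([_iround(p * len(minor_pool)) for p in minor_prevs])
            if block.group_size and block.group_size > 1:
                _choose_k_grouped(rng_matrix, major_pool, major_ks, X, col,
                                  block.group_size, block.group_overlap or 0.85)
                _choose_k_grouped(rng_matrix, minor_pool, minor_ks, X, col,
                                  block.group_size, block.group_overlap or 0.85)
            else:
                _choose_k_per_row(rng_matrix, major_pool, major_ks, X, col)
                _choose_k_per_row(rng_matrix, minor_pool, minor_ks, X, col)
        elif block.kind == "core":
            prevs = rng_matrix.uniform(block.prev_lo, block.prev_hi, size=m)
            for eco in ("HL", "LL"):
                pool = np.concatenate([pools[(eco, "train")], pools[(eco, "test")]])
                _choose_k_per_row(rng_matrix, pool,
                                  np.array([_iround(p * len(pool)) for p in prevs]), X, col)
        else:
            raise ConfigurationError(f"block_plan: unknown block kind {block.kind!r}")
        cluster_ids.extend(f"{block.name}_{i:05d}" for i in range(m))
        col += m

    assert col == total
    matrix = GeneClusterMatrix(meta["genome_id"].tolist(), cluster_ids, X)

    _check_quotas(cfg, matrix, meta)

    # depth, metrics, ANI on derived streams
    meta = simulate_depth(meta, cfg, seed=cfg.seed + 2)
    meta = _simulate_metrics(meta, cfg, seed=cfg.seed + 3)
    ani = simulate_ani(meta, cfg, seed=cfg.seed + 4)

    meta = meta.drop(columns=["stratum", "effective_clade", "effective_ecotype"])
    from .types import METADATA_COLUMNS
    meta = meta[METADATA_COLUMNS + ["subclade", "transitional"]]
    return matrix, meta, ani


def _check_quotas(cfg: SimulationConfig, matrix: GeneClusterMatrix, meta: pd.DataFrame) -> None:
    counts = matrix.presence.sum(axis=0)
    if cfg.rare_cluster_count is not None:
        rare = int((counts < cfg.rare_prevalence_max * matrix.n_genomes).sum())
        if rare != cfg.rare_cluster_count:
            raise ConfigurationError(
                f"rare_cluster_count: generated {rare} rare clusters, configured "
                f"{cfg.rare_cluster_count}; block quotas are inconsistent"
            )
    # marker training-stratum prevalences are exact by construction; verify
    id_to_col = {c: j for j, c in enumerate(matrix.cluster_ids)}
    for m in cfg.marker_plan:
        for eco, prev in (("HL", m.hl_prevalence), ("LL", m.ll_prevalence)):
            mask = ((meta["ecotype"] == eco) & (meta["stratum"] == "train")
                    & ~meta["transitional"]).to_numpy()
            if mask.sum() == 0:
                continue
            got = matrix.presence[mask, id_to_col[m.cluster_id]].sum()
            want = _iround(prev * mask.sum())
            if got != want:
                raise ConfigurationError(
                    f"marker_plan: {m.cluster_id} has {got} {eco} training carriers, expected {want}"
                )


# ---------------------------------------------------------------------------
# dropout
# ---------------------------------------------------------------------------

def apply_dropout(matrix: GeneClusterMatrix, metadata: pd.DataFrame, seed: int) -> GeneClusterMatrix:
    """Completeness-proportional gene loss.

    Each intrinsic presence survives iff a per-(genome, cluster) uniform draw
    ``u < completeness/100``.  Draws are a fixed function of ``(seed, genome
    position)``, so lowering one genome's completeness can only remove genes
    (monotone nesting) and absences never become presences.
    """
    comp = metadata.set_index("genome_id").loc[matrix.genome_ids, "completeness_pct"].to_numpy(float)
    if np.isnan(comp).any():
        raise ValueError("apply_dropout requires completeness for every genome")
    out = np.zeros_like(matrix.presence)
    p = matrix.n_clusters
    for i in range(matrix.n_genomes):
        u = np.random.default_rng([seed, i]).random(p)
        out[i] = matrix.presence[i] & (u < comp[i] / 100.0)
    return GeneClusterMatrix(matrix.genome_ids, matrix.cluster_ids, out)


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------

def simulate_depth(metadata: pd.DataFrame, cfg: SimulationConfig, seed: int) -> pd.DataFrame:
    """Fill ``depth_m``: clade mean + Gaussian noise, floored at 0 m.

    A quota of genomes (``cfg.n_missing_depth``) is left without a depth,
    emulating incomplete isolation metadata.
    """
    dm = cfg.depth_model
    hl_means = [dm.clade_means_m[c.label] for c in cfg.clade_plan if c.ecotype == "HL"]
    ll_means = [dm.clade_means_m[c.label] for c in cfg.clade_plan if c.ecotype == "LL"]
    if hl_means and ll_means and max(hl_means) >= min(ll_means):
        raise ConfigurationError("depth_model: HL clade mean depths must all lie above LL means")
    rng = np.random.default_rng(seed)
    meta = metadata.copy()
    means = meta["clade"].map(dm.clade_means_m).to_numpy(float)
    depth = np.maximum(0.0, means + rng.normal(0.0, dm.sd_m, size=len(meta)))
    if cfg.n_missing_depth > 0 and cfg.n_missing_depth < len(meta):
        missing = rng.choice(len(meta), size=cfg.n_missing_depth, replace=False)
        depth[missing] = np.nan
    meta["depth_m"] = depth
    in_range = ((depth >= 0) & (depth <= 150)).sum()
    logger.info("depth simulated: %d of %d depths within 0-150 m (quota %s)",
                in_range, int(np.isfinite(depth).sum()), cfg.depth_range_quota)
    return meta


def _simulate_metrics(metadata: pd.DataFrame, cfg: SimulationConfig, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    meta = metadata.copy()
    cols = ["genome_size_bp", "gc_pct", "coding_density", "hypothetical_fraction"]
    for c in cols:
        meta[c] = np.nan
    for clade, means in cfg.metric_model.means.items():
        sds = cfg.metric_model.sds[clade]
        mask = (meta["clade"] == clade).to_numpy()
        k = int(mask.sum())
        for j, c in enumerate(cols):
            meta.loc[mask, c] = rng.normal(means[j], sds[j], size=k)
    meta["coding_density"] = meta["coding_density"].clip(0, 1)
    meta["hypothetical_fraction"] = meta["hypothetical_fraction"].clip(0, 1)
    return meta


# ---------------------------------------------------------------------------
# ANI
# ---------------------------------------------------------------------------

def simulate_ani(metadata: pd.DataFrame, cfg: SimulationConfig, seed: int) -> ANITable:
    """Pairwise ANI values around the within/between-clade medians.

    Values are symmetric (emitted in both directions with equal value) and
    values below the reporting floor are censored to missing, mirroring how
    whole-genome ANI tools simply omit distant pairs.  Self-pairs are not
    emitted.
    """
    am = cfg.ani_model
    rng = np.random.default_rng(seed)
    ids = metadata["genome_id"].to_numpy()
    clades = metadata["clade"].to_numpy()
    n = len(ids)
    if n < 2:
        return ANITable()
    iu, ju = np.triu_indices(n, k=1)
    same = clades[iu] == clades[ju]
    base = np.where(same, am.within_median_pct, am.between_median_pct)
    vals = base + rng.normal(0.0, am.noise_sd_pct, size=len(iu))
    vals = np.clip(vals, 0.0, 100.0)
    censored = vals < am.reporting_floor_pct
    vals = np.where(censored, np.nan, vals)

    total = rng.integers(300, 601, size=len(iu))
    frac = np.clip((np.where(np.isnan(vals), am.reporting_floor_pct, vals) - 70.0) / 30.0, 0.05, 1.0)
    mapped = np.minimum(total, np.floor(total * frac).astype(int))

    df = pd.DataFrame({
        "query": ids[iu], "reference": ids[ju],
        "ani_pct": vals, "mapped": mapped, "total": total,
    })
    rev = df.rename(columns={"query": "reference", "reference": "query"})[ANITable.COLUMNS]
    out = pd.concat([df, rev], ignore_index=True)
    return ANITable(out)
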