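"""Statistical battery: per-cluster Fisher exact tests, BH correction,
within/between-clade ANI comparison, and rank-based genome-metric tests.

Conventions: the per-cluster 2x2 table is (present/absent) x (HL/LL); the
odds ratio is the unconditional sample OR ``(a*d)/(b*c)`` reported as
``+inf`` when one ecotype never carries the cluster while the other does
(the "mutually exclusive" signature); the two-sided exact p sums
hypergeometric probabilities no larger than the observed table's.  Dunn's
post-hoc z-tests use the pooled Kruskal-Wallis ranking with tie correction
and BH adjustment within each metric's family of pairwise comparisons.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import ANITable, GeneClusterMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "FisherResult", "ANIComparison", "MetricTestReport",
    "fisher_per_cluster", "bh_adjust", "ani_within_between", "metric_tests",
]

GENOME_METRICS = ["genome_size_bp", "gc_pct", "coding_density", "hypothetical_fraction"]


# ---------------------------------------------------------------------------
# Fisher exact per cluster
# ---------------------------------------------------------------------------

@dataclass
class FisherResult:
    cluster_id: str
    present_hl: int
    present_ll: int
    absent_hl: int
    absent_ll: int
    odds_ratio: float  # may be +inf
    infinite_or: bool
    p_value: float
    p_adjusted: float


def fisher_per_cluster(matrix: GeneClusterMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """Fisher's exact test of ecotype association for every gene cluster.

    Clusters absent from all genomes are skipped (logged).  Identical 2x2
    tables share one exact-test evaluation, which makes the genome-scale
    sweep cheap.  Returns a tidy frame with BH-adjusted p-values across all
    tested clusters.
    """
    eco = metadata.set_index("genome_id").loc[matrix.genome_ids, "ecotype"]
    if eco.isna().any():
        raise ValidationError("fisher_per_cluster: all genomes need an ecotype label")
    hl = (eco == "HL").to_numpy()
    n_hl, n_ll = int(hl.sum()), int((~hl).sum())
    if n_hl == 0 or n_ll == 0:
        raise ValidationError("fisher_per_cluster needs genomes from both ecotypes")

    a = matrix.presence[hl].sum(axis=0).astype(int)      # present, HL
    b = matrix.presence[~hl].sum(axis=0).astype(int)     # present, LL
    tested = (a + b) > 0
    skipped = int((~tested).sum())
    if skipped:
        logger.info("fisher_per_cluster: %d clusters absent everywhere, skipped", skipped)

    a_t, b_t = a[tested], b[tested]
    c_t, d_t = n_hl - a_t, n_ll - b_t

    # exact p per unique (a, b) table: margins are constant across clusters
    uniq, inverse = np.unique(np.stack([a_t, b_t], axis=1), axis=0, return_inverse=True)
    p_uniq = np.array([
        sps.fisher_exact([[ua, ub], [n_hl - ua, n_ll - ub]], alternative="two-sided")[1]
        for ua, ub in uniq
    ])
    pvals = np.clip(p_uniq[inverse], np.nextafter(0, 1), 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        ad = a_t.astype(float) * d_t
        bc = b_t.astype(float) * c_t
        orat = np.where(bc > 0, ad / np.where(bc > 0, bc, 1.0), np.inf)
        orat = np.where((bc == 0) & (ad == 0), np.nan, orat)
    infinite = (bc == 0) & (ad > 0)

    ids = np.asarray(matrix.cluster_ids, dtype=object)[tested]
    out = pd.DataFrame({
        "cluster_id": ids,
        "present_hl": a_t, "present_ll": b_t,
        "absent_hl": c_t, "absent_ll": d_t,
        "odds_ratio": orat, "infinite_or": infinite,
        "p_value": pvals,
        "p_adjusted": bh_adjust(pvals),
    })
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# ANI comparison
# ---------------------------------------------------------------------------

@dataclass
class ANIComparison:
    within_values: np.ndarray
    between_values: np.ndarray
    within_median_pct: float
    between_median_pct: float
    statistic: float
    p_value: float


def ani_within_between(ani: ANITable, metadata: pd.DataFrame) -> ANIComparison:
    """Compare reported ANI for within-clade vs between-clade genome pairs.

    Pairs are deduplicated to unordered form (symmetric tables contribute one
    value per pair), censored pairs are excluded from both groups, and the
    groups are compared with a two-sided Wilcoxon rank-sum test.
    """
    clade = metadata.set_index("genome_id")["clade"]
    rep = ani.reported().copy()
    if len(rep) == 0:
        raise ValidationError("no reported ANI values")
    key = np.where(rep["query"] < rep["reference"],
                   rep["query"] + "|" + rep["reference"],
                   rep["reference"] + "|" + rep["query"])
    rep = rep.assign(_pair=key).drop_duplicates("_pair")
    rep = rep[rep["query"] != rep["reference"]]
    cq = rep["query"].map(clade)
    cr = rep["reference"].map(clade)
    known = cq.notna() & cr.notna()
    rep, cq, cr = rep[known], cq[known], cr[known]
    same = (cq == cr).to_numpy()
    within = rep.loc[same, "ani_pct"].to_numpy(float)
    between = rep.loc[~same, "ani_pct"].to_numpy(float)
    if len(within) == 0 or len(between) == 0:
        raise ValidationError("need at least one reported within-clade and between-clade pair")
    if np.ptp(np.concatenate([within, between])) == 0:
        stat, p = 0.0, 1.0  # all values identical: no evidence of a shift
    else:
        res = sps.mannwhitneyu(within, between, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    return ANIComparison(
        within_values=within, between_values=between,
        within_median_pct=float(np.median(within)),
        between_median_pct=float(np.median(between)),
        statistic=stat, p_value=p,
    )


# ---------------------------------------------------------------------------
# genome-metric tests
# ---------------------------------------------------------------------------

@dataclass
class MetricTestReport:
    ecotype_tests: pd.DataFrame      # metric, statistic, p
    clade_tests: pd.DataFrame        # metric, H, p, clades tested
    dunn_tests: pd.DataFrame         # metric, clade_a, clade_b, z, p, p_adjusted
    untested_groups: Dict[str, list] = field(default_factory=dict)


def _dunn_pairwise(values: List[np.ndarray], labels: List[str]) -> pd.DataFrame:
    """Dunn's z statistics from the pooled ranking, with tie correction."""
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, sizes = [], []
    start = 0
    for v in values:
        mean_ranks.append(ranks[start:start + len(v)].mean())
        sizes.append(len(v))
        start += len(v)
    rows = []
    for i, j in itertools.combinations(range(len(values)), 2):
        se = np.sqrt(var_unit * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"clade_a": labels[i], "clade_b": labels[j],
                     "z": z, "p_value": min(max(p, np.nextafter(0, 1)), 1.0)})
    return pd.DataFrame(rows)


def metric_tests(metadata: pd.DataFrame, metrics: Optional[Sequence[str]] = None,
                 min_group: int = 3) -> MetricTestReport:
    """Rank-based comparisons of genome metrics by ecotype and clade.

    Per metric: Wilcoxon rank-sum across ecotypes; Kruskal-Wallis across
    clades with >= ``min_group`` members; Dunn post-hoc z-tests with BH
    adjustment within the metric's family.  Undersized clades are reported
    as untested rather than silently dropped.
    """
    metrics = list(metrics) if metrics is not None else GENOME_METRICS
    eco_rows, kw_rows, dunn_rows = [], [], []
    untested: Dict[str, list] = {}
    for metric in metrics:
        if metric not in metadata.columns:
            logger.warning("metric %s missing for all genomes, skipped", metric)
            continue
        vals = pd.to_numeric(metadata[metric], errors="coerce")
        ok = vals.notna()
        if not ok.any():
            logger.warning("metric %s missing for all genomes, skipped", metric)
            continue
        df = metadata.loc[ok, ["ecotype", "clade"]].assign(value=vals[ok])

        labeled = df[df["ecotype"].notna()]
        hl = labeled.loc[labeled["ecotype"] == "HL", "value"].to_numpy()
        ll = labeled.loc[labeled["ecotype"] == "LL", "value"].to_numpy()
        if len(hl) >= 2 and len(ll) >= 2:
            if np.ptp(np.concatenate([hl, ll])) == 0:
                stat, p = 0.0, 1.0
            else:
                res = sps.mannwhitneyu(hl, ll, alternative="two-sided")
                stat, p = float(res.statistic), float(res.pvalue)
            eco_rows.append({"metric": metric, "statistic": stat, "p_value": p})

        groups = {c: g["value"].to_numpy()
                  for c, g in df[df["clade"].notna()].groupby("clade")}
        small = sorted(c for c, v in groups.items() if len(v) < min_group)
        if small:
            untested[metric] = small
        big = {c: v for c, v in groups.items() if len(v) >= min_group}
        if len(big) >= 2:
            labels = sorted(big)
            arrays = [big[c] for c in labels]
            if np.ptp(np.concatenate(arrays)) == 0:
                H, p_kw = 0.0, 1.0
            else:
                H, p_kw = sps.kruskal(*arrays)
            kw_rows.append({"metric": metric, "H": float(H), "p_value": float(p_kw),
                            "clades": ",".join(labels)})
            dunn = _dunn_pairwise(arrays, labels)
            dunn["metric"] = metric
            dunn["p_adjusted"] = bh_adjust(dunn["p_value"].to_numpy())
            dunn_rows.append(dunn)

    return MetricTestReport(
        ecotype_tests=pd.DataFrame(eco_rows, columns=["metric", "statistic", "p_value"]),
        clade_tests=pd.DataFrame(kw_rows, columns=["metric", "H", "p_value", "clades"]),
        dunn_tests=(pd.concat(dunn_rows, ignore_index=True) if dunn_rows
                    else pd.DataFrame(columns=["clade_a", "clade_b", "z", "p_value",
                                               "metric", "p_adjusted"])),
        untested_groups=untested,
    )
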