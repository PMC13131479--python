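"""Configuration objects for the synthetic generator and the pipeline.

The synthetic generator is quota-driven: every gene-cluster block states
exactly how many clusters it contributes and how many carrier genomes each
cluster gets (deterministic counts, randomized placement).  The default
configuration is calibrated so that the headline dataset statistics hold as
exact equalities on any seed:

* 78,790 gene clusters in total, 76,764 of them present in <15% of genomes;
* a pair of divergent marker homologs at 94%/0% (HL/LL) and 5%/95%
  training-stratum prevalence;
* exactly 6,622 clusters survive the "present in >=5% of either ecotype"
  frequency filter;
* a ~60:40 HL:LL class balance with a high-completeness (>75%) training
  stratum and a fragmented (25-75%) test stratum.

The calibration arithmetic: with 264 HL and 176 LL genomes the filter keeps a
cluster iff it has >=14 HL carriers or >=9 LL carriers, and a cluster is
"rare" iff it has <=65 carriers overall.  Blocks are sized so that 72,168
ultra-rare clusters fall below both keep thresholds, 4,596 clusters are rare
but kept, and 2,026 clusters are common (>=66 carriers): 76,764 rare and
6,622 kept, exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

__all__ = [
    "ConfigurationError",
    "CladeSpec",
    "MarkerSpec",
    "BlockSpec",
    "CompletenessPlan",
    "TransitionalPlan",
    "DepthModel",
    "ANIModel",
    "MetricModel",
    "SimulationConfig",
    "ModelConfig",
    "PipelineConfig",
    "default_simulation_config",
    "default_pipeline_config",
    "load_pipeline_config",
    "save_pipeline_config",
]


class ConfigurationError(ValueError):
    """A configuration failed validation; the message names the field."""


@dataclass
class CladeSpec:
    label: str
    ecotype: str  # "HL" / "LL"
    n_train: int  # genomes with completeness > 75
    n_test: int   # genomes with completeness in [25, 75]
    n_subclades: int = 1  # finer population structure within the clade

    @property
    def n_genomes(self) -> int:
        return self.n_train + self.n_test


@dataclass
class MarkerSpec:
    """A planted marker cluster with exact training-stratum prevalences."""

    cluster_id: str
    hl_prevalence: float
    ll_prevalence: float


@dataclass
class BlockSpec:
    """A quota block of gene clusters sharing one placement rule.

    kind:
      ``ultra_rare``  carriers drawn from ``carrier_choices`` (any genome);
      ``clade``       ``carrier_count`` carriers within one clade;
      ``subclade``    per-cluster prevalence in [prev_lo, prev_hi] of one
                      subclade of ``clade`` (subclades cycled per cluster);
      ``ecotype``     per-cluster prevalence in [prev_lo, prev_hi] of one ecotype;
      ``shared``      leaning block: major ecotype prevalence in
                      [prev_lo, prev_hi], minor = major - minor_offset;
      ``core``        prevalence in [prev_lo, prev_hi] of *both* ecotypes.
    """

    name: str
    kind: str
    n_clusters: int
    clade: Optional[str] = None
    carrier_count: Optional[int] = None
    ecotype: Optional[str] = None
    prev_lo: Optional[float] = None
    prev_hi: Optional[float] = None
    minor_offset: Optional[float] = None
    carrier_choices: Optional[tuple] = None
    choice_weights: Optional[tuple] = None
    # correlated-cassette structure: clusters come in groups whose carrier
    # sets overlap (linked-gene blocks); None places every cluster independently
    group_size: Optional[int] = None
    group_overlap: Optional[float] = None


@dataclass
class CompletenessPlan:
    """Per-stratum completeness quotas: evenly spaced values, shuffled over genomes."""

    train_range: tuple = (76.0, 100.0)  # completeness > 75
    test_range: tuple = (25.0, 75.0)    # completeness in [25, 75]


@dataclass
class TransitionalPlan:
    """HL test genomes planted with a low-light gene profile.

    These emulate "transitional" isolates whose gene content resembles the
    opposite ecotype; downstream classifiers misclassify them HL->LL.
    """

    n_genomes: int = 4
    source_clade: str = "HLII"      # true clade of the transitional genomes
    effective_clade: str = "LLI"    # clade whose gene profile they receive


@dataclass
class DepthModel:
    """Per-clade depth of isolation: clade mean + Gaussian noise, floored at 0 m."""

    clade_means_m: dict = field(default_factory=dict)
    sd_m: float = 40.0


@dataclass
class ANIModel:
    within_median_pct: float = 91.1
    between_median_pct: float = 79.8
    noise_sd_pct: float = 1.5
    reporting_floor_pct: float = 75.0


@dataclass
class MetricModel:
    """Per-clade genome-metric means; ``sds`` shares keys with ``means``.

    means[clade] = (genome_size_bp, gc_pct, coding_density, hypothetical_fraction)
    """

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)


@dataclass
class SimulationConfig:
    n_genomes: int
    hl_fraction: float
    total_clusters: int
    # None skips the exact rare-band check (tiny ad-hoc configs)
    rare_cluster_count: Optional[int]
    rare_prevalence_max: float
    clade_plan: list
    marker_plan: list
    homolog_pairs: list
    block_plan: list
    completeness_plan: CompletenessPlan
    transitional_plan: TransitionalPlan
    dropout_mode: str  # "none" | "bernoulli"
    depth_model: DepthModel
    depth_range_quota: tuple  # (count within 0-150 m, total with depth)
    n_missing_depth: int
    ani_model: ANIModel
    metric_model: MetricModel
    batch_weights: dict
    reduced_feature_target: int
    seed: int

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.n_genomes <= 0:
            raise ConfigurationError("n_genomes: must be positive")
        if not (0 <= self.hl_fraction <= 1):
            raise ConfigurationError("hl_fraction: must lie in [0, 1]")
        if self.rare_cluster_count is not None and self.rare_cluster_count > self.total_clusters:
            raise ConfigurationError("rare_cluster_count: exceeds total_clusters")
        if not (0 < self.rare_prevalence_max <= 1):
            raise ConfigurationError("rare_prevalence_max: must lie in (0, 1]")
        if self.dropout_mode not in ("none", "bernoulli"):
            raise ConfigurationError(f"dropout_mode: unknown mode {self.dropout_mode!r}")

        clade_total = sum(c.n_genomes for c in self.clade_plan)
        if clade_total != self.n_genomes:
            raise ConfigurationError(
                f"clade_plan: quotas sum to {clade_total}, expected n_genomes={self.n_genomes}"
            )
        hl_total = sum(c.n_genomes for c in self.clade_plan if c.ecotype == "HL")
        if abs(hl_total / self.n_genomes - self.hl_fraction) > 0.02:
            raise ConfigurationError(
                f"clade_plan: HL share {hl_total / self.n_genomes:.3f} "
                f"inconsistent with hl_fraction={self.hl_fraction}"
            )
        for c in self.clade_plan:
            if c.ecotype not in ("HL", "LL"):
                raise ConfigurationError(f"clade_plan: ecotype {c.ecotype!r} for clade {c.label}")
            if not c.label.startswith(c.ecotype):
                raise ConfigurationError(
                    f"clade_plan: clade label {c.label!r} does not carry ecotype prefix {c.ecotype}"
                )
            if c.n_train < 0 or c.n_test < 0:
                raise ConfigurationError(f"clade_plan: negative quota for clade {c.label}")

        n_hl_train = sum(c.n_train for c in self.clade_plan if c.ecotype == "HL")
        n_ll_train = sum(c.n_train for c in self.clade_plan if c.ecotype == "LL")
        for m in self.marker_plan:
            for prev, stratum, n in (
                (m.hl_prevalence, "HL", n_hl_train),
                (m.ll_prevalence, "LL", n_ll_train),
            ):
                if not (0 <= prev <= 1):
                    raise ConfigurationError(
                        f"marker_plan: {m.cluster_id} {stratum} prevalence {prev} outside [0, 1]"
                    )
                if round(prev * n) > n:
                    raise ConfigurationError(
                        f"marker_plan: {m.cluster_id} quota exceeds {stratum} training stratum"
                    )
        marker_ids = {m.cluster_id for m in self.marker_plan}
        for a, b in self.homolog_pairs:
            if a not in marker_ids or b not in marker_ids:
                raise ConfigurationError(f"homolog_pairs: ({a}, {b}) not both in marker_plan")

        n_block = sum(b.n_clusters for b in self.block_plan) + len(self.marker_plan)
        if n_block != self.total_clusters:
            raise ConfigurationError(
                f"block_plan: blocks + markers provide {n_block} clusters, "
                f"expected total_clusters={self.total_clusters}"
            )
        clade_labels = {c.label for c in self.clade_plan}
        for b in self.block_plan:
            if b.kind in ("clade", "subclade") and b.clade not in clade_labels:
                raise ConfigurationError(f"block_plan: unknown clade {b.clade!r} in block {b.name}")
            if b.kind in ("ecotype", "shared") and b.ecotype not in ("HL", "LL"):
                raise ConfigurationError(f"block_plan: block {b.name} needs an ecotype")
            if b.kind in ("ecotype", "shared", "core", "subclade"):
                if b.prev_lo is None or b.prev_hi is None or not (0 <= b.prev_lo <= b.prev_hi <= 1):
                    raise ConfigurationError(f"block_plan: bad prevalence range in block {b.name}")

        missing = [c.label for c in self.clade_plan if c.label not in self.depth_model.clade_means_m]
        if missing:
            raise ConfigurationError(f"depth_model: no mean depth for clades {missing}")
        am = self.ani_model
        if not (am.within_median_pct > am.between_median_pct > am.reporting_floor_pct):
            raise ConfigurationError(
                "ani_model: need within median > between median > reporting floor, got "
                f"{am.within_median_pct} / {am.between_median_pct} / {am.reporting_floor_pct}"
            )


@dataclass
class ModelConfig:
    """Supervised-model settings shared by classification and regression."""

    n_estimators: int = 500        # trees in final random forests
    tune_trees: int = 50           # smaller forests used during grid search
    # features per split, preferred first when cross-validation ties: with
    # >90% of clusters being ultra-rare noise, a larger candidate pool per
    # split is the robust choice for p >> n sparse binary data
    rf_feature_grid: tuple = ("p10", "sqrt", "p3")
    lr_c_grid: tuple = (0.01, 0.1, 1.0)             # inverse penalty for elastic-net LR
    en_alpha_grid: tuple = (0.001, 0.01, 0.1, 1.0)  # penalty for elastic-net regression
    l1_ratio: float = 0.5


@dataclass
class PipelineConfig:
    simulation: SimulationConfig
    train_threshold: float = 75.0
    completeness_floor: float = 25.0
    cv_folds: int = 5
    resamples: int = 10
    model: ModelConfig = field(default_factory=ModelConfig)
    reduction_cutoff: float = 0.05
    n_components: int = 50
    consensus_top_k: int = 20
    consensus_min_frequency: float = 0.8
    consensus_require_both: bool = True
    n_permutations: int = 50
    stats_alpha: float = 0.05
    stats_min_group: int = 3
    embed_neighbors: int = 15
    embed_min_dist: float = 0.1
    seed: int = 1


# ---------------------------------------------------------------------------
# defaults
# ---------------------------------------------------------------------------

def default_clade_plan() -> list:
    return [
        CladeSpec("HLI", "HL", 38, 62, n_subclades=2),
        CladeSpec("HLII", "HL", 62, 102, n_subclades=3),
        CladeSpec("LLI", "LL", 24, 46, n_subclades=2),
        CladeSpec("LLII/III", "LL", 19, 37, n_subclades=2),
        CladeSpec("LLIV", "LL", 17, 33, n_subclades=2),
    ]


def default_marker_plan() -> list:
    # The pepA-like divergent homolog pair plus ten invented high-gap markers.
    # Training strata are 100 HL / 60 LL genomes, so every quota below is an
    # integer count and the prevalences are exact.  LL markers sit at 0.80-0.90
    # so that forest training keeps probing several of them per branch, which
    # is what lets fragmented low-light genomes still be recognized.
    return [
        MarkerSpec("marker_pepA_HL", 0.94, 0.00),
        MarkerSpec("marker_pepA_LL", 0.05, 0.95),
        MarkerSpec("marker_hl_01", 0.88, 0.00),
        MarkerSpec("marker_hl_02", 0.92, 0.00),
        MarkerSpec("marker_hl_03", 0.96, 0.00),
        MarkerSpec("marker_hl_04", 1.00, 0.00),
        MarkerSpec("marker_hl_05", 0.90, 0.00),
        MarkerSpec("marker_ll_01", 0.00, 0.80),
        MarkerSpec("marker_ll_02", 0.00, 0.85),
        MarkerSpec("marker_ll_03", 0.00, 0.90),
        MarkerSpec("marker_ll_04", 0.00, 0.85),
        MarkerSpec("marker_ll_05", 0.00, 0.80),
    ]


def default_block_plan() -> list:
    return [
        # --- ultra-rare tail: below the keep threshold in both ecotypes ---
        BlockSpec("ultra_rare", "ultra_rare", 72168,
                  carrier_choices=(1, 2), choice_weights=(0.6, 0.4)),
        # --- rare but kept (total carriers <= 65): clade + subclade blocks
        BlockSpec("clade_HLI", "clade", 350, clade="HLI", carrier_count=60),
        BlockSpec("clade_HLII", "clade", 350, clade="HLII", carrier_count=65),
        BlockSpec("clade_LLI", "clade", 350, clade="LLI", carrier_count=42),
        BlockSpec("clade_LLII/III", "clade", 350, clade="LLII/III", carrier_count=34),
        BlockSpec("clade_LLIV", "clade", 350, clade="LLIV", carrier_count=30),
        BlockSpec("subclade_HLI", "subclade", 250, clade="HLI",
                  prev_lo=0.55, prev_hi=0.85),
        BlockSpec("subclade_HLII", "subclade", 250, clade="HLII",
                  prev_lo=0.55, prev_hi=0.85),
        BlockSpec("subclade_LLI", "subclade", 250, clade="LLI",
                  prev_lo=0.55, prev_hi=0.85),
        BlockSpec("subclade_LLII/III", "subclade", 250, clade="LLII/III",
                  prev_lo=0.55, prev_hi=0.85),
        BlockSpec("subclade_LLIV", "subclade", 250, clade="LLIV",
                  prev_lo=0.55, prev_hi=0.85),
        BlockSpec("hl_accessory_rare", "ecotype", 800, ecotype="HL",
                  prev_lo=0.10, prev_hi=0.24),
        BlockSpec("ll_accessory_rare", "ecotype", 796, ecotype="LL",
                  prev_lo=0.15, prev_hi=0.35),
        # --- common (total carriers >= 66) --------------------------------
        BlockSpec("hl_accessory_common", "ecotype", 450, ecotype="HL",
                  prev_lo=0.45, prev_hi=0.55),
        BlockSpec("ll_accessory_common", "ecotype", 500, ecotype="LL",
                  prev_lo=0.42, prev_hi=0.52),
        BlockSpec("shared_hl_leaning", "shared", 350, ecotype="HL",
                  prev_lo=0.55, prev_hi=0.80, minor_offset=0.35),
        BlockSpec("shared_ll_leaning", "shared", 350, ecotype="LL",
                  prev_lo=0.55, prev_hi=0.80, minor_offset=0.35),
        BlockSpec("core", "core", 364, prev_lo=0.95, prev_hi=1.00),
    ]


def default_depth_model() -> DepthModel:
    return DepthModel(
        clade_means_m={
            "HLI": 25.0,
            "HLII": 40.0,
            "LLI": 75.0,
            "LLII/III": 100.0,
            "LLIV": 125.0,
        },
        sd_m=40.0,
    )


def default_metric_model() -> MetricModel:
    # (genome size bp, GC %, coding density, hypothetical fraction)
    means = {
        "HLI": (1.65e6, 30.8, 0.90, 0.26),
        "HLII": (1.68e6, 31.2, 0.90, 0.25),
        "LLI": (1.90e6, 35.0, 0.89, 0.28),
        "LLII/III": (2.05e6, 36.5, 0.88, 0.30),
        "LLIV": (2.45e6, 50.0, 0.87, 0.33),  # LLIV GC displaced from other LL clades
    }
    sds = {
        "HLI": (5e4, 0.5, 0.010, 0.02),
        "HLII": (5e4, 0.5, 0.010, 0.02),
        "LLI": (7e4, 0.6, 0.010, 0.02),
        "LLII/III": (8e4, 0.7, 0.010, 0.02),
        "LLIV": (1e5, 0.8, 0.010, 0.02),
    }
    return MetricModel(means=means, sds=sds)


def default_simulation_config(seed: int = 1) -> SimulationConfig:
    cfg = SimulationConfig(
        n_genomes=440,
        hl_fraction=0.6,
        total_clusters=78790,
        rare_cluster_count=76764,
        rare_prevalence_max=0.15,
        clade_plan=default_clade_plan(),
        marker_plan=default_marker_plan(),
        homolog_pairs=[("marker_pepA_HL", "marker_pepA_LL")],
        block_plan=default_block_plan(),
        completeness_plan=CompletenessPlan(),
        transitional_plan=TransitionalPlan(),
        dropout_mode="bernoulli",
        depth_model=default_depth_model(),
        depth_range_quota=(406, 427),
        n_missing_depth=13,
        ani_model=ANIModel(),
        metric_model=default_metric_model(),
        batch_weights={"BATCH_A": 0.6, "BATCH_B": 0.25, "BATCH_C": 0.15},
        reduced_feature_target=6622,
        seed=seed,
    )
    cfg.validate()
    return cfg


def default_pipeline_config(seed: int = 1) -> PipelineConfig:
    return PipelineConfig(simulation=default_simulation_config(seed), seed=seed)


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

_NESTED = {
    "clade_plan": CladeSpec,
    "marker_plan": MarkerSpec,
    "block_plan": BlockSpec,
}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    for key, cls in _NESTED.items():
        d[key] = [cls(**_tupleize(cls, item)) for item in d[key]]
    d["homolog_pairs"] = [tuple(p) for p in d["homolog_pairs"]]
    d["completeness_plan"] = CompletenessPlan(
        train_range=tuple(d["completeness_plan"]["train_range"]),
        test_range=tuple(d["completeness_plan"]["test_range"]),
    )
    d["transitional_plan"] = TransitionalPlan(**d["transitional_plan"])
    d["depth_model"] = DepthModel(**d["depth_model"])
    d["ani_model"] = ANIModel(**d["ani_model"])
    mm = d["metric_model"]
    d["metric_model"] = MetricModel(
        means={k: tuple(v) for k, v in mm["means"].items()},
        sds={k: tuple(v) for k, v in mm["sds"].items()},
    )
    d["depth_range_quota"] = tuple(d["depth_range_quota"])
    return SimulationConfig(**d)


def _tupleize(cls, item: dict) -> dict:
    out = dict(item)
    for f in dataclasses.fields(cls):
        v = out.get(f.name)
        if isinstance(v, list):
            out[f.name] = tuple(v)
    return out


def pipeline_config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    d["simulation"] = simulation_config_from_dict(d["simulation"])
    model = d.get("model", {})
    d["model"] = ModelConfig(**_tupleize(ModelConfig, model))
    return PipelineConfig(**d)


def save_pipeline_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=False)


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    cfg = pipeline_config_from_dict(d)
    cfg.simulation.validate()
    return cfg
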