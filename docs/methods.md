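# Methods

`panecotype` models a genotype-to-phenotype analysis of *Prochlorococcus*
light ecotypes: given binary gene presence/absence profiles from a pangenome
of ~440 isolate genomes of very uneven assembly quality, can high-light (HL)
vs low-light (LL) adaptation be predicted, which gene clusters carry the
signal, and how do phylogenetic clades structure genome content and
similarity?  Because the real collection consists of hundreds of external
assemblies, the package pairs every analysis stage with a calibrated
synthetic-data generator so that the whole pipeline is testable at desk
scale.

## The synthetic collection

### Genomes

The default collection has 440 genomes in five clades with a 60:40
HL:LL balance:

| clade    | ecotype | train (>75%) | test (25–75%) | subclades |
|----------|---------|--------------|----------------|-----------|
| HLI      | HL      | 38           | 62             | 2         |
| HLII     | HL      | 62           | 102            | 3         |
| LLI      | LL      | 24           | 46             | 2         |
| LLII/III | LL      | 19           | 37             | 2         |
| LLIV     | LL      | 17           | 33             | 2         |

Each clade is further partitioned into balanced subclades with private gene
blocks, mirroring the within-clade substructure visible in real
gene-content embeddings.

Completeness scores (BUSCO-like, %) are evenly spaced within each stratum
and shuffled across genomes, so the stratum sizes are exact: 160 training
genomes above 75% and 280 test genomes in [25, 75].  The training strata
were sized at 100 HL / 60 LL so that the planted marker prevalences below
are exact percentages (94% of 100, 95% of 60), rather than matching any
particular external collection's counts.

Four HL test genomes are *transitional*: they keep their HL label and clade
assignment but receive the gene profile of an LL clade.  They are the
genomes every classifier misclassifies HL→LL, reproducing the
directionality of misclassification seen when genotypically intermediate
isolates are forced into a binary ecotype scheme.

### Gene clusters

The 78,790 gene clusters are generated in quota blocks: each block fixes
the number of clusters and each cluster's carrier count; randomness only
decides *which* genomes carry it.  Collection-level counts are therefore
exact on every seed.  With 264 HL and 176 LL genomes, the ecotype-
conditional frequency filter (drop clusters below 5% prevalence in both
ecotypes) keeps a cluster iff it has ≥14 HL or ≥9 LL carriers, and a
cluster is "rare" (<15% prevalence) iff it has ≤65 carriers.  The default
block plan:

* **ultra-rare tail** — 72,168 clusters carried by 1–2 genomes (60/40
  split), below both filter thresholds; this reproduces the overwhelming
  singleton/doubleton accessory tail of the genus.
* **clade blocks** — 350 clusters per clade, carried by 60/65/42/34/30
  genomes of their clade (≤65 total: rare but kept), plus 250 subclade
  clusters per clade at 55–85% prevalence of one subclade.  Together they
  give each clade (and subclade) a private gene complement and drive the
  clade-level substructure in embeddings.
* **ecotype-exclusive accessory** — rare tier: 800 HL clusters at 10–24%
  of HL genomes and 796 LL clusters at 15–35% of LL genomes (≤65 carriers);
  common tier: 450 HL clusters at 45–55% and 500 LL clusters at 42–52%
  (≥66 carriers).  Exclusive means zero carriers in the other ecotype:
  together with the markers these are the "mutually exclusive" clusters
  that return infinite odds ratios in the Fisher screen.
* **shared, ecotype-biased** — 2×350 clusters present in both ecotypes
  with a 35-point prevalence offset (majority side 55–80%).
* **core** — 364 clusters at 95–100% prevalence in both ecotypes.  The
  small size of this block reflects how poorly a classical core genome is
  recovered for this genus.
* **planted markers** — 12 singleton clusters with exact training-stratum
  prevalences: the divergent homolog pair (94%/0% HL/LL and 5%/95%), five
  further HL markers at 88–100%/0%, and five LL markers at 0%/80–90%.
  Genome-level misclassification (majority vote across all fits) is then
  confined to the transitional genomes — the HL→LL direction — although
  individual fits may still miscall one or two of the most fragmented
  low-light genomes.

Totals: 72,168 + 4,596 rare-kept + 2,026 common = 78,790 clusters;
76,764 rare; 6,622 survive the frequency filter — all exact equalities.

The generator can also place clusters in correlated groups
(`BlockSpec.group_size`), emulating linked cassettes whose members
co-occur; the default plan places every cluster independently.

#### Why the block plan looks the way it does

Two requirements pull against each other.  (1) Genomes in the test stratum
have lost 25–75% of their genes, so classification must survive on a
minority sample of the signal: that demands *redundant* ecotype evidence
(the exclusive accessory tiers).  (2) The planted markers must dominate
random-forest impurity importances, which demands that no large block sit
at marker-level Gini gain.  The resolution: the exclusive backbone is
capped at ~55% prevalence (well below the markers), and the LL markers sit
at 80–90% rather than ~100%.  The latter matters for a subtle reason:
when a marker is nearly universal in training, the "marker absent" branch
of a decision tree runs out of training genomes of that class after one or
two splits and terminates in majority-class leaves, so fragmented genomes
that happen to have lost that one marker are misclassified.  At 80–90%
prevalence the absent branch stays populated, trees probe several markers
and then the accessory backbone, and fragmented genomes get many chances
to reveal their class.

### Dropout (fragmentation)

A genome at completeness *c* retains each intrinsic gene independently with
probability *c*/100.  The per-(genome, cluster) uniform draws are a fixed
function of the seed and the genome's position, so lowering one genome's
completeness only ever removes genes (monotone nesting) and absences never
become presences.  `simulate_collection` returns the intrinsic matrix;
`apply_dropout` produces the observed one.  All exact-count statements
above refer to the intrinsic matrix; models train and test on the observed
one.  This is deliberately the simplest fragmentation model — real
assembly gaps are contiguous and biased, not i.i.d. — so passing tests
show robustness to *random* gene loss, not to structured loss.

### Depth, metrics, ANI

* **Depth of isolation**: clade mean (HLI 25, HLII 40, LLI 75, LLII/III
  100, LLIV 125 m) + Gaussian noise (sd 40 m), floored at 0 m; 13 genomes
  lack depth.  The means/sd were chosen so HL clades are shallower than LL
  clades, ~95% of depths fall in the photic 0–150 m band, and the
  best achievable regression RMSE is the noise sd (~40 m) — i.e. genotype
  determines the clade mean but not the individual depth, which is what
  makes depth regression "poor" relative to the depth range and makes
  predictions near-constant within a clade.
* **Genome metrics** (genome size, GC%, coding density, hypothetical-gene
  fraction): per-clade Gaussians.  Values follow genus knowledge
  qualitatively: HL genomes ~1.65–1.7 Mb at ~31% GC; LL larger and
  GC-richer, with LLIV displaced to ~50% GC and ~2.45 Mb.
* **ANI**: every unordered genome pair draws its value from a Gaussian
  centred on the within-clade (91.1%) or between-clade (79.8%) median with
  sd 1.5; values under the 75% reporting floor are censored to missing, as
  ANI tools do; tables are emitted symmetrically in both directions.
  Noise sd 1.5 keeps censoring rare enough that the recovered medians stay
  within ±0.05 of the planted values while between-clade pairs still
  occasionally censor.

## Pipeline stages

* **Frequency filter** — drop a cluster iff prevalence < cutoff (default
  5%) in *both* ecotypes; exactly at the cutoff is kept.  Idempotent, and
  computed on whatever genome set is supplied.
* **Projection** — PCA with 50 components, fitted on the training stratum
  only (no leakage), refit once per resample; binary features are centered
  but not variance-scaled; component signs are fixed by making each
  loading's largest-magnitude entry positive.
* **Supervised evaluation** — train on completeness > 75, test on
  [25, 75] (both boundary values land in test), genomes under 25% excluded.
  5-fold CV × 10 resamples; resample *r* seeds with `base_seed + r`.
  Classification optimizes MCC; regression minimizes RMSE (meters).
  Random forests: 500 trees, information-gain (entropy) splitting — with
  the 60:40 class imbalance, entropy penalizes impure majority-skewed
  leaves harder than Gini, which measurably reduces low-light
  misclassification of heavily fragmented genomes; features-per-split
  tuned over {p/10, √p, p/3} with CV ties resolving to the first entry
  (p/10 — preferred because >90% of features are ultra-rare noise, where a
  larger candidate pool per split is the established recommendation); grid
  search runs 50-tree forests, final per-fold fits 500.  Linear models:
  elastic-net (mixing 0.5), penalty C ∈ {0.01, 0.1, 1} for logistic
  classification, α ∈ {0.001 … 1} for regression; importance is
  |coefficient| × training-stratum feature SD.  Every fold's final model
  is also scored on the whole test stratum, with predictions and
  importances recorded per fit.
* **Permutation null** — permutation *i* (seed `base_seed + 1000 + i`)
  uniformly permutes the training-stratum labels, preserving the 60:40
  balance exactly; `fraction_correct` is the proportion of assigned
  training labels left unchanged.  Each permutation is fit with the five
  CV-fold models (default hyper-parameters — a null needs no grid search)
  and each fold model is scored on the fragmented test stratum against the
  *true* labels; the record carries the mean fold score.  This measures
  how much genuine predictive signal survives training on mostly wrong
  labels, which is what makes permuted-model skill track residual label
  correctness.  The correlation analysis uses the elastic-net family: its
  response to residual alignment is graded, whereas a forest's
  majority-vote response is close to a step function of the alignment,
  which caps the achievable Pearson correlation near √(2/π) ≈ 0.8
  irrespective of the data (a known property of sign-like responses to a
  Gaussian driver).
* **Consensus** — per fit, the top-20 features by importance (ties broken
  by id); a feature is consensus if it appears in ≥80% of fits of *both*
  model families; annotated with per-ecotype prevalence and a
  mutually-exclusive flag.
* **Statistics** — per-cluster Fisher exact tests (two-sided
  "probability at most observed"; sample odds ratio with an explicit
  infinity flag, no continuity correction), BH adjustment across all
  tested clusters; identical 2×2 tables share one evaluation, which makes
  the 78,790-cluster sweep take seconds.  ANI comparison deduplicates
  symmetric pairs, excludes censored ones, and uses a two-sided Wilcoxon
  rank-sum test.  Genome metrics: rank-sum by ecotype, Kruskal–Wallis by
  clade, Dunn post-hoc z-tests from the pooled tie-corrected ranking with
  BH within each metric's family; clades under 3 genomes are reported
  untested.
* **Embedding** — UMAP (15 neighbors, min-dist 0.1) on exact Jaccard
  distances computed via dot products and passed as a precomputed metric,
  which also makes the embedding reproducible from the seed.  Separation
  under a labeling is the mean silhouette; singleton classes are excluded.

## Numerical conventions

* MCC returns 0 when any denominator factor is zero; an all-zero
  confusion table is an error.
* Quota counts round half-up; marker quotas that cannot be met raise a
  configuration error naming the offending field.
* BH adjustment requires p ∈ (0, 1]; Fisher p-values are clipped away
  from 0 before adjustment.
* All randomness flows from explicit integer seeds; generation,
  model training, permutation and embedding are bitwise reproducible.

## Problem sizes

The default configuration *is* the full study scale (440 genomes ×
78,790 clusters); the classification, permutation and consensus stages run
it outright.  Worked examples shrink only the ultra-rare tail (2,168
instead of 72,168 clusters), which carries no class signal, to keep the
demonstration scripts snappy.

## Known limitations

* Dropout is i.i.d. per gene; real fragmentation is contiguous and biased
  toward certain genomic regions.
* ANI is generated from a two-level (within/between clade) model; real
  collections grade ANI by phylogenetic distance continuously, and
  between-clade-within-ecotype pairs would sit above between-ecotype
  pairs.
* The ecotype signal is planted as exchangeable exclusive/biased blocks;
  real pangenomes entangle phylogenetic and ecological structure, so a
  classifier's performance here is an upper bound on what equally sized
  real data would give.
* Genome metrics and per-clade depth means are invented (only their
  qualitative ordering is grounded); no conclusions should be read from
  their absolute values.
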