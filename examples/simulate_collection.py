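"""Generate the default paper-scale synthetic collection and report its shape.

The default configuration reproduces the headline dataset statistics exactly:
78,790 gene clusters, 76,764 of them in <15% of genomes, a 60:40 HL:LL
balance, and the divergent marker-homolog pair at 94%/0% and 5%/95%
training-stratum prevalence.
"""

from panecotype import reduce_by_frequency, simulate_collection
from panecotype.config import default_simulation_config

cfg = default_simulation_config(seed=1)
matrix, metadata, ani = simulate_collection(cfg)

counts = matrix.presence.sum(axis=0)
rare = int((counts / matrix.n_genomes < 0.15).sum())
reduced, report = reduce_by_frequency(matrix, metadata, cutoff=0.05)

print(f"genomes:            {matrix.n_genomes} "
      f"({(metadata.ecotype == 'HL').sum()} HL / {(metadata.ecotype == 'LL').sum()} LL)")
print(f"gene clusters:      {matrix.n_clusters}")
print(f"rare (<15%):        {rare}")
print(f"after 5% filter:    {reduced.n_clusters}")

train = metadata["completeness_pct"] > 75
hl = metadata["ecotype"] == "HL"
col = {c: j for j, c in enumerate(matrix.cluster_ids)}
pepa_hl = matrix.presence[(train & hl).to_numpy(), col["marker_pepA_HL"]].mean()
pepa_ll = matrix.presence[(train & ~hl).to_numpy(), col["marker_pepA_LL"]].mean()
print(f"HL homolog prevalence in HL training genomes: {pepa_hl:.0%}")
print(f"LL homolog prevalence in LL training genomes: {pepa_ll:.0%}")
print(f"ANI rows (both directions, censored pairs blank): {len(ani)}")

# The counts above are quota-exact: rerunning with any seed reproduces them,
# only the placement of genes across genomes changes.
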