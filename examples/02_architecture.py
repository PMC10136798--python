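"""Profile host-gene architecture: flanking-intron lengths and asymmetry.

Simulates a cohort whose hosts carry upstream/downstream flanking introns
drawn with means 11251/6089 bp (an asymmetric, knockdown-like
architecture), then summarizes the recovered lengths against background
genes and tests the upstream-vs-downstream asymmetry.
"""

from circarch import architecture, classify
from circarch.simulate import SimConfig, simulate_genome

config = SimConfig(n_host_genes=150, n_background_genes=100,
                   host_flank_up_mean=11251, host_flank_down_mean=6089, seed=2)
genes, _, truth, junctions = simulate_genome(config)

circs = classify.classify_all(junctions, genes)
by_id = {g.gene_id: g for g in genes}
records = architecture.build_records(circs, by_id)
background = [g for g in genes if g.gene_id not in set(records.host_gene_id)]

summary = architecture.summarize(records, background)
print(summary[summary.length_class.isin(["upstream_intron", "downstream_intron",
                                         "intron"])].to_string(index=False))

asym = architecture.asymmetry(records)
print(f"\nflank asymmetry: up {asym['mean_up']:.0f} bp vs down {asym['mean_down']:.0f} bp"
      f"  ratio {asym['ratio']:.2f}  paired p = {asym['p']:.2e}")

# The recovered means should sit within sampling error of the planted
# 11251/6089 bp, the background mean near 1832 bp, and the paired test
# should reject symmetry — the architecture signature of backsplicing
# without the pausing machinery that normally compensates for it.
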