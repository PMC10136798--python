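# circarch

Analysis toolkit for studying how chromatin factors — PARP1 in the
motivating system, *Drosophila* S2 cells — shape **circular RNA (circRNA)
biogenesis** through gene architecture and RNA polymerase II transcriptional
dynamics.

circRNAs arise when a downstream splice donor is joined back to an upstream
acceptor (*backsplicing*). Whether a gene backsplices depends on a
space–time balance: *cis* features that bring the splice sites together
(long flanking introns, repeat elements, RNA-binding-protein motifs,
G-quadruplexes) and the *time* RNAPII spends transcribing them (pausing).
`circarch` implements the full desk-side analysis of that model:

- **Junction classification** (`circarch.classify`) — backsplice junction
  calls (seekCRIT-style TSV) are classified against a GTF annotation as
  *exonic single*, *exonic multi* (boundaries coincide with annotated exon
  starts/ends of one transcript), *intronic* (lariat-derived, strictly
  inside one intron), or *unassigned*; host genes are assigned with a
  smallest-span tie rule, and 2/3-way condition overlaps are tabulated.
- **Host-gene architecture** (`circarch.architecture`) — gene, circle-exon,
  internal-intron, and flanking-intron lengths per condition vs background
  genes; Welch/Student tests and paired upstream-vs-downstream asymmetry
  (ratio of means, paired t on per-circle differences).
- **Flanking-sequence bias** (`circarch.seqbias`) — a G-quadruplex scanner
  (k ≥ 4 runs of r ≥ 3 G, loops of 1–7 non-G bases; left-greedy, maximal,
  non-overlapping), motifs/kb densities, windowed nucleotide composition,
  repeat-class bp-fraction enrichment with bootstrap CIs, and a symmetric
  RBP-motif binomial test with BH correction.
- **RNAPII pausing** (`circarch.pausing`) — pausing indices from
  strand-resolved nascent-RNA coverage (bedGraph pairs) over a
  circRNA-anchored schema: first exon **E1**, acceptor **A**, internal
  **I**, donor **D**, downstream exon **dsE**, each with ±300 bp flanks.
  Index = region mean / gene-body mean (within-condition profiles) or
  / annotated-genome mean ("track", for cross-condition deltas); changes
  are classed increased/decreased/no-change at |log2 Δ| > log2 1.5.
- **Circular-to-linear output** (`circarch.nanostring`) — nCounter-style
  probe counts (circular-junction + linear-junction probe per gene) are
  normalized by housekeeping geometric means; per-probe
  log2FC = log2(mean+½) − log2(mean_ref+½) with Welch tests and BH;
  genes are *altered* at |log2FC| > 2, p < 0.05; the C:L change
  Δ_CL = log2FC_circ − log2FC_linear classes each gene, and classes are
  cross-tabulated against pausing changes (Fisher/χ²).
- **Synthetic data with ground truth** (`circarch.simulate`) — a seeded
  generator emits GTF/FASTA/junction-TSV/repeat-BED/bedGraph/probe-TSV
  bundles: host genes with long (optionally asymmetric) lognormal flanking
  introns, planted G4s and repeats, per-region Poisson pause multipliers,
  and negative-binomial probe effects — every planted value recorded in a
  JSON sidecar for recovery testing.

## Worked example

```python
from collections import Counter
from circarch import classify
from circarch.simulate import SimConfig, simulate_bundle

bundle = simulate_bundle(SimConfig(n_host_genes=12, n_background_genes=30, seed=7))
circs = classify.classify_all(bundle.junctions, bundle.genes)
print(Counter(c.circ_class for c in circs))
```

prints

```
Counter({'exonic_multi': 10, 'intronic': 3, 'exonic_single': 2})
```

— 15 planted junctions, each recovered in its planted class (the
generator's ground truth makes this checkable: see
`examples/01_simulate_and_classify.py`). The other example scripts walk
through architecture summaries (planted flank means 11251/6089 bp
recovered with an asymmetry ratio ≈ 1.86, paired p ≈ 2e-10), planted
repeat folds and G4 densities, WT-vs-KD pausing metaprofiles (planted
acceptor-exon pausing 3× in WT shifting to donor-downstream 3× in KD),
and the 26-gene probe panel (27% of hosts altered under PARylation
inhibition vs 69% under knockdown; C:L classes 19/50/31).

Each stage is also exposed as a thin CLI:

```bash
circarch simulate --outdir sim --seed 7
circarch classify --gtf sim/annotation.gtf --junctions sim/junctions.tsv --out classified.tsv
circarch run --config run.yaml      # full pipeline with a JSON report
```

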