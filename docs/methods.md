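# Methods

This note documents the models, estimators, and numerical conventions the
package implements, the design choices made where the procedure was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Coordinate model and classification

All coordinates are 0-based half-open internally; GTF (1-based inclusive)
is converted at the I/O boundary and is the only 1-based surface. Each
gene is reduced to one representative transcript — the longest genomic
span, ties broken by lexicographic transcript id — because the analysis
is gene-level, not isoform-level. Exons and introns are kept in
transcript (5′→3′) orientation, so "upstream" and "downstream" are
strand-aware everywhere; a strand-flip of the whole annotation leaves
every length statistic unchanged.

A backsplice junction spans genomic `[start, end)`. It is **exonic** when
`start` matches an annotated exon start and `end` an exon end of the same
representative transcript (exact match by default; a bp tolerance is
exposed for noisy callers), **intronic** when both ends fall strictly
inside one intron, otherwise **unassigned** — never an error, since
junctions outside genes are expected in real calls. When several genes
match (nested or overlapping loci), the gene with the smallest span wins;
the rule is deterministic and order-independent. Junction *identity* is
(chrom, start, end, strand); per-condition "unique" tallies count
condition-exclusive identities, and 2- or 3-set Venn partitions are
computed by exact set algebra with duplicate inputs deduplicated under a
warning.

## Architecture statistics

Per exonic circRNA: host-gene length, circle-exon lengths, internal
intron lengths, and the flanking introns (transcript-5′ of the acceptor
exon; transcript-3′ of the donor). Flanks at gene termini are flagged
undefined and excluded from means — never imputed. Genes hosting several
distinct circles contribute one record per circle, matching a
per-circle flank analysis. Group comparisons default to Welch's t on
log lengths (intron lengths are heavy-tailed, roughly lognormal); a
Student's t on raw lengths is available for parity with analyses of raw
means. Asymmetry reports mean(up)/mean(down) with a paired t on per-circle
(up − down); an unpaired variant is provided since pairing is a choice,
not a given. Zero-variance degenerate inputs return p = 1 when means are
equal.

## G-quadruplex scanning

Motif: k ≥ 4 runs of r ≥ 3 guanines with loops of 1–7 bases ("R4"
defaults; all three exposed). **Loops may not contain guanine.** This is
the one place the package sharpens the usual informal definition: if
loops may contain G, the decomposition of a G-rich tract into runs and
loops is ambiguous and the scan result depends on a regex engine's
backtracking order. Restricting loops to non-G bases makes the
decomposition unique, so "left-greedy, maximal, non-overlapping" is well
defined and bit-reproducible: the scanner chains consecutive maximal
G-runs (a run < r or a gap > 7 breaks the chain) and emits every chain of
≥ k runs. The suite proves this scanner equal to an independent greedy
regex oracle on thousands of G/C-rich random sequences. Minus-strand
motifs are the mirrored C-run pattern on the reference; N never matches a
run. Density is motifs per kb of pooled region length.

## Repeat and motif enrichment

Repeat enrichment is measured in covered-bp *fractions* (robust to
fragmented annotations): per class, fraction of flank-intron bp covered
by that class over the same fraction in background introns, reported
separately for upstream and downstream flanks. The 95% CI comes from
resampling introns (B = 1000, seeded); a class absent from the background
yields an undefined fold, flagged rather than infinite. The RBP-motif
test is a deliberately simple occurrence analogue, not a positional
meta-profile: IUPAC motifs are counted (overlapping matches included) in
each flank set, tested one-sided binomial against the background per-bp
rate, BH-corrected across motifs; a motif is *symmetric* when significant
in both flanks. Background and flank windows default to whole introns,
with a window override.

## Pausing indices

The pausing index of a region is its mean per-base nascent coverage
divided by a normalizer. Two normalizers are provided because they answer
different questions:

- **gene_body** (default for within-condition profiles): region mean /
  gene-span mean. Scale-invariant per gene; uniform coverage gives
  exactly 1 everywhere; genes with zero body coverage are excluded, never
  ε-filled.
- **track**: region mean / mean over all annotated gene bodies. Used for
  cross-condition deltas. This is not optional pedantry: with gene-body
  normalization, the bp-weighted mean of a gene's pooled exon and intron
  indices is identically 1 in every condition, so exonic and intronic
  pausing of one gene can never both increase between conditions — yet
  both-increased genes are exactly what a redistribution-plus-occupancy
  change produces. Track normalization keeps absolute occupancy changes
  visible; the cohort's unchanged genes anchor the normalizer.

The region schema per host circle labels E1 (first exon, omitted with a
flag when the acceptor *is* the first exon), A, I (internal exons,
pooled), D, dsE (omitted when the donor is last), plus ±300 bp flanks of
each labelled exon, clipped against already-labelled regions so labels
never overlap; for single-exon circles A and D name the same exon
(flagged). Deltas are log2((index_alt + ε)/(index_ref + ε)), ε = 1e−6,
classed increased/decreased/no-change at |Δ| > τ = log2 1.5 — a threshold
chosen so Poisson noise at the generator's default depth (20 reads/bp)
does not flip classes; it is configurable.

## Probe-count analysis

Normalization follows standard digital-counting practice: per-sample
factor = grand geometric mean of housekeeping counts / that sample's
housekeeping geometric mean (housekeeping probes with any zero count are
dropped from factor computation with a warning). Note the reference
includes all samples, so normalized housekeeping geometric means are
equalized exactly, and an outlier sample shifts the grand mean slightly
rather than being scaled purely against the others. log2FC uses a 0.5
pseudo-count; p-values are Welch tests on log2(count + ½) replicates, BH
across probes. With three replicates the Welch test is mildly
conservative under the null (the suite measures ≈3–4% of null probes at
p < 0.05); the BH-level altered rate stays controlled at α. A gene is
*altered* when either probe passes |log2FC| > 2 and p < 0.05 (q optional).
C:L classes use Δ_CL = log2FC_circ − log2FC_linear with δ = 1 (2-fold)
and require the circular change itself to be significant. The
pausing-association cross-tab uses Fisher's exact test for 2×2 tables and
the χ² contingency test otherwise.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions. Lengths are lognormal, parameterized by the arithmetic mean
and a log-scale dispersion (default 0.6) — the distribution family is a
modelling choice; only means are anchored. Defaults: background introns
1832 bp; background exons 292 bp (the source material is ambiguous about
whether 292 bp is the genome-wide or circle-exon mean, so the value is
configurable and documented rather than silently resolved); host flanks
9131/9355 bp (upstream/downstream), with asymmetric presets such as
11251/6089 bp exercised in tests; 4–9 exons per gene, about half the
genes on the minus strand, one synthetic chromosome by default
(multi-chromosome via config). Host circles pick an internal
acceptor–donor exon pair so both flanks exist.

Planted sequence features: G4 motifs are written into intron sequence
with non-G buffer zones (8 bases, the loop limit + 1) on both sides so no
neighbouring G-run can chain into a planted motif — making recovery at
*exactly* the recorded coordinates a hard test, not a statistical one.
Defaults plant 0.2 motifs/kb in host flanks vs 0.5/kb in background
introns, emulating host-gene G4 depletion. Repeats are annotation
intervals (BED) with exact per-intron bp budgets: background fractions
Satellite/LINE 2%, LTR 1%, simple repeats 5%, with flank folds 3×/2×/2×/
0.5× — enrichment of transposable and satellite elements, loss of simple
repeats. Coverage is per-base Poisson at depth × region multiplier; the
default multipliers encode early pausing in WT (E1, A at 3×) and
donor-downstream accumulation in KD (dsE at 3×). Probe counts are
negative binomial (mean 500, dispersion 0.1, variance m + φm²); at φ = 0
counts equal rounded means exactly, a deterministic limit used in tests.
Every planted value lands in a JSON ground-truth sidecar, and a fixed
seed determines every emitted byte.

**What the generator does not emulate:** read-level errors and alignment
ambiguity, junction-caller false positives, isoform diversity,
expression-level variation between genes (coverage depth is uniform
unless configured), realistic karyotypes, sequence-dependent coverage
bias, and batch effects in probe counts. Passing recovery tests therefore
demonstrates the estimators' correctness under the stated statistical
model, not robustness to upstream artifacts in real libraries.

## Benchmark cohorts

`circarch.cohorts` builds small deterministic datasets whose outputs are
known by construction, used to pin expected counts end to end: a
284-junction table over 116 host genes (70 intronic / 214 exonic,
condition-exclusive 26/21/23 and 67/87/60), skipped-exon overlap sets
(38/422 → 9.0%, 42/471 → 8.9%), a 26-gene probe panel whose planted
effects yield 27%/69% altered genes and C:L classes 19/50/31, and a
WT/KD coverage pair realizing exon pausing-change percentages
57.7/11.5/30.8 and intron 53.8/34.6/11.5. Only the marginal class
compositions are specified for the pausing panel; the joint exon×intron
assignment uses one margin-consistent table (12/3/0; 1/2/0; 1/4/3).
Replicates in the probe panel are deterministic mean multiples
(0.94/1.00/1.06), so null probes give p = 1 exactly and planted ±3 log2
effects are detected with near-zero p.

## Problem sizes

Defaults throughout were chosen as the smallest cohorts whose sampling
error is well inside the tested tolerances: recovery tests use 40–60 host
genes × 20 seeds (flanks, multipliers) or 8 probes × 20 seeds (effects);
oracle-equivalence suites use 1000 × 2 kb sequences; the null control
uses 1000 simulated panels of 10 genes. The acceptance script uses single
runs with larger cohorts (400–600 genes) for tighter point estimates.

## Known limitations

- Exact-boundary matching (tolerance 0) mirrors annotation-locked
  junction callers; callers reporting shifted boundaries need the
  tolerance raised, which can create multi-gene ambiguity resolved only
  by the span rule.
- The motif test ignores position within the intron; a positional
  meta-profile would detect near-splice-site clustering this test cannot.
- The pausing schema pools internal exons; per-exon internal profiles are
  not produced.
- Fisher's exact test is only applied to 2×2 cross-tabs; larger tables
  fall back to χ², which is approximate at small n.
- The C:L significance rule keys on the circular probe; a gene whose
  linear probe alone changes direction is classed by Δ_CL magnitude only.
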