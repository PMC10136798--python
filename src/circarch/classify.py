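"""Backsplice-junction classification against gene models.

A junction is *exonic* when its boundaries coincide with an annotated exon
start and exon end of the same representative transcript (single- vs
multi-exon by whether acceptor and donor are the same exon), *intronic*
when both boundaries fall strictly inside one intron (lariat-derived
ciRNA), and *unassigned* otherwise. Ambiguous multi-gene matches resolve
to the gene with the smallest genomic span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from intervaltree import IntervalTree

from .model import GeneModel, Interval, JunctionCall

INTRONIC = "intronic"
EXONIC_SINGLE = "exonic_single"
EXONIC_MULTI = "exonic_multi"
UNASSIGNED = "unassigned"
CLASSES = (INTRONIC, EXONIC_SINGLE, EXONIC_MULTI, UNASSIGNED)


@dataclass
class CircRNA:
    """A classified backsplice junction."""

    junction: JunctionCall
    circ_class: str = UNASSIGNED
    host_gene_id: Optional[str] = None
    acceptor_exon_index: Optional[int] = None  # transcript orientation, 0-based
    donor_exon_index: Optional[int] = None
    internal_exons: list[Interval] = field(default_factory=list)
    internal_introns: list[Interval] = field(default_factory=list)

    @property
    def identity(self) -> tuple:
        return self.junction.identity

    @property
    def condition(self) -> str:
        return self.junction.condition

    @property
    def is_exonic(self) -> bool:
        return self.circ_class in (EXONIC_SINGLE, EXONIC_MULTI)

    @property
    def exon_span(self) -> Interval:
        j = self.junction
        return Interval(j.chrom, j.start, j.end, j.strand)


class GeneIndex:
    """Interval index over gene spans for overlap queries."""

    def __init__(self, genes: Iterable[GeneModel]) -> None:
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        self.by_id = {g.gene_id: g for g in self.genes}
        for g in self.genes:
            span = g.span
            self._trees.setdefault(g.chrom, IntervalTree()).addi(span.start, span.end, g)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda g: (g.length, g.gene_id))


def _match_gene(junction: JunctionCall, gene: GeneModel, tol: int) -> Optional[CircRNA]:
    """Try to classify ``junction`` against one gene; None if no match."""
    if gene.strand != junction.strand:
        return None
    if junction.strand == "+":
        acc = gene.exon_index_genomic_start(junction.start, tol)
        don = gene.exon_index_genomic_end(junction.end, tol)
    else:
        acc = gene.exon_index_genomic_end(junction.end, tol)
        don = gene.exon_index_genomic_start(junction.start, tol)
    if acc is not None and don is not None and acc <= don:
        cls = EXONIC_SINGLE if acc == don else EXONIC_MULTI
        internal_exons = gene.exons[acc + 1 : don]
        internal_introns = gene.introns[acc:don]
        return CircRNA(junction, cls, gene.gene_id, acc, don,
                       list(internal_exons), list(internal_introns))
    for intron in gene.introns:
        if intron.start < junction.start and junction.end < intron.end:
            return CircRNA(junction, INTRONIC, gene.gene_id)
    return None


def classify(junction: JunctionCall, genes: GeneIndex | Iterable[GeneModel],
             tol: int = 0) -> CircRNA:
    """Classify one junction; exonic matches beat intronic, ties by span."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    candidates = index.overlapping(junction.chrom, junction.start, junction.end)
    exonic_hit = None
    intronic_hit = None
    for gene in candidates:  # sorted by (span, gene_id): first hit wins ties
        hit = _match_gene(junction, gene, tol)
        if hit is None:
            continue
        if hit.is_exonic and exonic_hit is None:
            exonic_hit = hit
        elif hit.circ_class == INTRONIC and intronic_hit is None:
            intronic_hit = hit
    return exonic_hit or intronic_hit or CircRNA(junction)


def classify_all(junctions: Iterable[JunctionCall], genes: Iterable[GeneModel] | GeneIndex,
                 tol: int = 0) -> list[CircRNA]:
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [classify(j, index, tol) for j in junctions]


def assign_host_gene(circ: CircRNA, genes: GeneIndex | Iterable[GeneModel],
                     tol: int = 0) -> Optional[str]:
    """Host gene of a circRNA (re-derived if the record lacks one)."""
    if circ.host_gene_id is not None:
        return circ.host_gene_id
    return classify(circ.junction, genes, tol).host_gene_id


def circs_to_table(circs: Iterable[CircRNA]) -> pd.DataFrame:
    rows = []
    for c in circs:
        j = c.junction
        rows.append(
            {
                "chrom": j.chrom, "start": j.start, "end": j.end, "strand": j.strand,
                "condition": j.condition, "circ_class": c.circ_class,
                "host_gene": c.host_gene_id or "",
                "acceptor_exon_index": "" if c.acceptor_exon_index is None else c.acceptor_exon_index,
                "donor_exon_index": "" if c.donor_exon_index is None else c.donor_exon_index,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Condition overlap (Venn partitions)


def condition_overlap(sets: dict[str, Iterable]) -> dict[frozenset, int]:
    """Venn partition counts for 2 or 3 labelled identifier collections.

    Returns a map from the frozenset of labels whose sets contain an
    identifier (and no others) to the count of such identifiers. Works for
    junction identities, host genes, DEG lists, or AS-gene lists alike.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("condition_overlap needs 2 or 3 labelled sets")
    clean: dict[str, set] = {}
    for label, items in sets.items():
        items = list(items)
        uniq = set(items)
        if len(uniq) < len(items):
            warnings.warn(f"duplicate identifiers in set {label!r}; deduplicated")
        clean[label] = uniq
    labels = sorted(clean)
    universe = set().union(*clean.values())
    out: dict[frozenset, int] = {}
    from itertools import combinations

    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            out[frozenset(combo)] = 0
    for item in universe:
        membership = frozenset(l for l in labels if item in clean[l])
        out[membership] += 1
    return out


def overlap_summary(partition: dict[frozenset, int]) -> dict[str, int]:
    """Readable labels: 'A' for exclusive to A, 'A&B' for shared, etc."""
    return {"&".join(sorted(k)): v for k, v in sorted(partition.items(), key=lambda kv: sorted(kv[0]))}


# ---------------------------------------------------------------------------
# Skipped-exon / circRNA overlap


def splice_overlap_report(as_genes: set, host_genes: set,
                          skipped_exon_events: Iterable[tuple[str, Interval]],
                          circs: Iterable[CircRNA]) -> dict:
    """How often does a circRNA coincide with a skipped exon?

    Counts genes that are alternatively spliced, genes producing circRNAs,
    their intersection, and AS genes with a skipped-exon interval exactly
    equal to some circRNA's exonic span. Percentages are over the AS gene
    set, reported to one decimal.
    """
    as_genes = set(as_genes)
    host_genes = set(host_genes)
    circ_spans: dict[str, set[tuple[int, int, str]]] = {}
    for c in circs:
        if c.host_gene_id is None:
            continue
        j = c.junction
        circ_spans.setdefault(c.host_gene_id, set()).add((j.start, j.end, j.chrom))
    matched = set()
    for gene, iv in skipped_exon_events:
        if gene in as_genes and (iv.start, iv.end, iv.chrom) in circ_spans.get(gene, set()):
            matched.add(gene)
    n_as = len(as_genes)
    pct = round(100.0 * len(matched) / n_as, 1) if n_as else 0.0
    return {
        "n_as_genes": n_as,
        "n_host_genes": len(host_genes),
        "n_as_and_host": len(as_genes & host_genes),
        "n_skipped_exon_circ_match": len(matched),
        "pct_skipped_exon_circ_match": pct,
    }
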