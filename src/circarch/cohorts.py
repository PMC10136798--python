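"""Deterministic benchmark cohorts with known class composition.

These builders construct small, fully specified datasets — gene models,
junction tables, probe-count matrices, and coverage track pairs — whose
classification and summary outputs are known by construction. They are
used to exercise every classifier and summarizer end to end and to pin
expected counts and percentages in tests; compositions default to the
study conditions (condition-exclusive junction tallies, a 26-gene probe
panel, and margin-specified pausing-change classes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genomeio import CoverageTrack
from .model import GeneModel, Interval, JunctionCall
from .classify import CircRNA, EXONIC_MULTI
from .nanostring import CIRC, HOUSEKEEPING, LINEAR, ProbeCountMatrix

_REP_MULTIPLIERS = (0.94, 1.0, 1.06)  # symmetric around 1, mean exactly 1


def _uniform_gene(gene_id: str, chrom: str, offset: int, n_exons: int = 8,
                  exon_len: int = 200, intron_len: int = 500,
                  strand: str = "+") -> GeneModel:
    exons = []
    pos = offset
    for _ in range(n_exons):
        exons.append(Interval(chrom, pos, pos + exon_len, strand))
        pos += exon_len + intron_len
    return GeneModel(gene_id, f"{gene_id}.t1", chrom, strand, exons)


# ---------------------------------------------------------------------------
# Junction-classification benchmark


def junction_benchmark(exonic_per_condition: dict[str, int] | None = None,
                       intronic_per_condition: dict[str, int] | None = None,
                       n_host_genes: int = 116
                       ) -> tuple[list[GeneModel], list[JunctionCall]]:
    """Genes plus condition-exclusive junction calls with known classes.

    Defaults: 67/87/60 exonic and 26/21/23 intronic junctions exclusive
    to WT/PARPi/KD, spread over 116 host genes.
    """
    if exonic_per_condition is None:
        exonic_per_condition = {"WT": 67, "PARPi": 87, "KD": 60}
    if intronic_per_condition is None:
        intronic_per_condition = {"WT": 26, "PARPi": 21, "KD": 23}
    genes = [
        _uniform_gene(f"host{i + 1:04d}", "chrB", offset=i * 7000,
                      strand="+" if i % 2 == 0 else "-")
        for i in range(n_host_genes)
    ]
    # distinct junction variants per gene, keyed by per-gene serial number
    exonic_pairs = [(1, 1), (2, 4), (1, 3)]  # (acceptor, donor) exon indices
    intronic_offsets = [(10, 60), (120, 240), (300, 420)]

    labels = [("exonic", cond) for cond, n in exonic_per_condition.items() for _ in range(n)]
    labels += [("intronic", cond) for cond, n in intronic_per_condition.items() for _ in range(n)]

    junctions = []
    serial = {g.gene_id: {"exonic": 0, "intronic": 0} for g in genes}
    for idx, (kind, cond) in enumerate(labels):
        gene = genes[idx % n_host_genes]
        variant = serial[gene.gene_id][kind]
        serial[gene.gene_id][kind] += 1
        if kind == "exonic":
            acc, don = exonic_pairs[variant]
            circ_exons = gene.exons[acc : don + 1]
            start = min(e.start for e in circ_exons)
            end = max(e.end for e in circ_exons)
        else:
            intron = gene.introns[5]
            off_s, off_e = intronic_offsets[variant]
            start, end = intron.start + off_s, intron.start + off_e
        junctions.append(JunctionCall(gene.chrom, start, end, gene.strand,
                                      condition=cond, gene_hint=gene.gene_id))
    return genes, junctions


# ---------------------------------------------------------------------------
# Skipped-exon overlap benchmark


def splice_overlap_benchmark(n_as_genes: int, n_circ_hosts: int, n_matching: int
                             ) -> tuple[set, set, list, list]:
    """(as_genes, host_genes, skipped_exon_events, circs) with a known
    fraction of AS genes whose skipped exon equals a circRNA span."""
    if not n_matching <= n_circ_hosts <= n_as_genes:
        raise ValueError("need n_matching <= n_circ_hosts <= n_as_genes")
    as_genes = {f"as{i + 1:04d}" for i in range(n_as_genes)}
    host_genes = set()
    events = []
    circs = []
    for i in range(n_as_genes):
        gene = f"as{i + 1:04d}"
        circ_span = Interval("chrA", 1000 + i * 5000, 1400 + i * 5000, "+")
        if i < n_circ_hosts:
            host_genes.add(gene)
            j = JunctionCall(circ_span.chrom, circ_span.start, circ_span.end, "+",
                            condition="KD", gene_hint=gene)
            circs.append(CircRNA(j, EXONIC_MULTI, gene, 1, 2))
        if i < n_matching:
            events.append((gene, circ_span))  # skipped exon == circRNA span
        elif i < n_circ_hosts:
            shifted = Interval(circ_span.chrom, circ_span.start + 2000,
                               circ_span.end + 2000, "+")
            events.append((gene, shifted))  # AS event elsewhere in the gene
    return as_genes, host_genes, events, circs


# ---------------------------------------------------------------------------
# Probe-count benchmark (26-gene panel)


def probe_panel_design(n_genes: int = 26) -> pd.DataFrame:
    """Planted circular-probe log2 effects per condition for the panel.

    Composition (circ probe; linear probes carry no effect):
      KD:    genes 1-5 at +3, genes 6-18 at -3, rest 0
             -> 18/26 genes altered; C:L 5 increased / 13 decreased / 8 no_change
      PARPi: genes 1-4 at +3, genes 6-8 at -3 -> 7/26 altered
      KDi:   genes 1-14 as in KD, genes 19-23 at +3 -> 19/26 altered
    """
    rows = []
    for i in range(n_genes):
        g = i + 1
        kd = 3.0 if g <= 5 else (-3.0 if g <= 18 else 0.0)
        parpi = 3.0 if g <= 4 else (-3.0 if 6 <= g <= 8 else 0.0)
        if g <= 14:
            kdi = kd
        elif 19 <= g <= 23:
            kdi = 3.0
        else:
            kdi = 0.0
        rows.append({"gene_id": f"ns{g:02d}", "KD": kd, "PARPi": parpi, "KDi": kdi})
    return pd.DataFrame(rows)


def probe_count_benchmark(n_genes: int = 26, base_mean: float = 500.0,
                          hk_mean: float = 800.0, n_housekeeping: int = 5
                          ) -> ProbeCountMatrix:
    """Deterministic probe counts realizing :func:`probe_panel_design`.

    Replicates are the mean scaled by fixed multipliers, so null probes
    have identical replicate vectors in every condition (p = 1) and
    planted effects are detected with near-zero p.
    """
    design = probe_panel_design(n_genes)
    conditions = ["WT", "PARPi", "KD", "KDi"]
    rows = []
    for _, d in design.iterrows():
        for ptype in (CIRC, LINEAR):
            row = {"probe_id": f"{d.gene_id}_{ptype}", "gene_id": d.gene_id,
                   "probe_type": ptype}
            for cond in conditions:
                eff = float(d[cond]) if (ptype == CIRC and cond != "WT") else 0.0
                mean = base_mean * 2.0**eff
                for rep, mult in enumerate(_REP_MULTIPLIERS, start=1):
                    row[f"{cond}_{rep}"] = int(mean * mult + 0.5)
            rows.append(row)
    for h in range(n_housekeeping):
        row = {"probe_id": f"hk{h + 1}", "gene_id": f"hk{h + 1}",
               "probe_type": HOUSEKEEPING}
        for cond in conditions:
            for rep, mult in enumerate(_REP_MULTIPLIERS, start=1):
                row[f"{cond}_{rep}"] = int(hk_mean * mult + 0.5)
        rows.append(row)
    return ProbeCountMatrix(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Pausing-change benchmark


#: joint (exon_class, intron_class) gene counts consistent with the
#: marginal compositions 15/3/8 (exons) and 14/9/3 (introns) over 26 genes
PAUSING_JOINT = [
    (("increased", "increased"), 12),
    (("increased", "decreased"), 3),
    (("decreased", "increased"), 1),
    (("decreased", "decreased"), 2),
    (("no_change", "increased"), 1),
    (("no_change", "decreased"), 4),
    (("no_change", "no_change"), 3),
]

_MULT = {"increased": 4.0, "decreased": 0.25, "no_change": 1.0}


def pausing_benchmark(n_background: int = 100, depth: float = 10.0
                      ) -> tuple[list[GeneModel], list[GeneModel],
                                 CoverageTrack, CoverageTrack, pd.DataFrame]:
    """26 panel genes plus background genes and a WT/KD track pair.

    KD coverage scales each panel gene's exonic and intronic bases by the
    multiplier of its planted class; background genes are unchanged and
    anchor the track-level normalizer. Returns (panel_genes, all_genes,
    track_wt, track_kd, expected_classes).
    """
    chrom = "chrP"
    panel = []
    expected = []
    gene_no = 0
    for (ex_cls, in_cls), count in PAUSING_JOINT:
        for _ in range(count):
            gene_no += 1
            gid = f"ns{gene_no:02d}"
            panel.append(_uniform_gene(gid, chrom, offset=(gene_no - 1) * 4000,
                                       n_exons=4, exon_len=300, intron_len=500))
            expected.append({"gene_id": gid, "exon_change": ex_cls,
                             "intron_change": in_cls})
    background = [
        _uniform_gene(f"pbg{i + 1:03d}", chrom, offset=(26 + i) * 4000,
                      n_exons=4, exon_len=300, intron_len=500)
        for i in range(n_background)
    ]
    all_genes = panel + background
    length = (26 + n_background) * 4000 + 4000
    wt_arr = np.zeros(length)
    kd_arr = np.zeros(length)
    exp_by_gene = {e["gene_id"]: e for e in expected}
    for gene in all_genes:
        span = gene.span
        wt_arr[span.start:span.end] = depth
        kd_arr[span.start:span.end] = depth
        if gene.gene_id in exp_by_gene:
            e = exp_by_gene[gene.gene_id]
            for exon in gene.exons:
                kd_arr[exon.start:exon.end] = depth * _MULT[e["exon_change"]]
            for intron in gene.introns:
                kd_arr[intron.start:intron.end] = depth * _MULT[e["intron_change"]]
    track_wt, track_kd = CoverageTrack(), CoverageTrack()
    for arr, track in ((wt_arr, track_wt), (kd_arr, track_kd)):
        track.set_array(chrom, "+", arr.copy())
        track.set_array(chrom, "-", np.zeros(length))
    return panel, all_genes, track_wt, track_kd, pd.DataFrame(expected)
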