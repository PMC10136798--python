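"""RNAPII pausing indices over a circRNA-anchored region schema.

Regions per host gene: E1 (first exon, when distinct from the acceptor),
A (circRNA acceptor exon), I (internal circRNA exons, pooled), D (donor
exon; equal to A for single-exon circles), dsE (first exon downstream of
the donor), plus +/-300 bp flanks of each labelled exon, clipped so that
labels never overlap. All labels are in transcript orientation.

The pausing index of a region is its mean per-base nascent coverage
divided by a normalizer: the gene-body mean by default (within-condition
profiles), or the mean over all annotated gene bodies ("track"
normalization) for cross-condition comparisons, where per-gene
normalization would cancel the very occupancy changes being measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .classify import CircRNA
from .genomeio import CoverageTrack
from .model import GeneModel, Interval

CORE_LABELS = ("E1", "A", "I", "D", "dsE")
INCREASED = "increased"
DECREASED = "decreased"
NO_CHANGE = "no_change"
DEFAULT_TAU = math.log2(1.5)
EPS = 1e-6


@dataclass
class RegionSchema:
    gene_id: str
    regions: dict[str, list[Interval]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def labels(self) -> list[str]:
        return [lab for lab in self.regions if self.regions[lab]]


def _clip_flank(iv_start: int, iv_end: int, blocked: list[Interval], chrom: str,
                strand: str) -> Optional[Interval]:
    """Clip a flank window against already-labelled exons."""
    for b in blocked:
        if b.start < iv_end and iv_start < b.end:
            # shrink toward whichever side remains
            if iv_start < b.start:
                iv_end = min(iv_end, b.start)
            else:
                iv_start = max(iv_start, b.end)
    if iv_start >= iv_end:
        return None
    return Interval(chrom, iv_start, iv_end, strand)


def define_regions(circ: CircRNA, gene: GeneModel, flank: int = 300) -> RegionSchema:
    """Label the E1/A/I/D/dsE schema for one exonic circRNA."""
    if not circ.is_exonic:
        raise ValueError("region schema applies to exonic circRNAs only")
    acc, don = circ.acceptor_exon_index, circ.donor_exon_index
    schema = RegionSchema(gene_id=gene.gene_id)
    exon_for: dict[str, list[Interval]] = {}
    if acc > 0:
        exon_for["E1"] = [gene.exons[0]]
    else:
        schema.flags.append("E1_is_acceptor")
    exon_for["A"] = [gene.exons[acc]]
    exon_for["I"] = list(gene.exons[acc + 1 : don])
    if acc == don:
        schema.flags.append("single_exon_circ")  # A and D name the same exon
    exon_for["D"] = [gene.exons[don]]
    if don < gene.n_exons - 1:
        exon_for["dsE"] = [gene.exons[don + 1]]
    else:
        schema.flags.append("donor_is_last_exon")
    blocked = list(dict.fromkeys(iv for ivs in exon_for.values() for iv in ivs))
    schema.regions.update(exon_for)
    span = gene.span
    for label in [lab for lab in ("E1", "A", "I", "D", "dsE") if lab in exon_for]:
        ups, dns = [], []
        for e in exon_for[label]:
            left = _clip_flank(max(e.start - flank, span.start), e.start,
                               blocked, gene.chrom, gene.strand)
            if left:
                blocked.append(left)
            right = _clip_flank(e.end, min(e.end + flank, span.end),
                                blocked, gene.chrom, gene.strand)
            if right:
                blocked.append(right)
            genomic_up, genomic_dn = (left, right) if gene.strand == "+" else (right, left)
            if genomic_up:
                ups.append(genomic_up)
            if genomic_dn:
                dns.append(genomic_dn)
        schema.regions[f"{label}_up{flank}"] = ups
        schema.regions[f"{label}_dn{flank}"] = dns
    return schema


def pausing_index(track: CoverageTrack, regions: Iterable[Interval],
                  norm_mean: float) -> float:
    """Mean region coverage divided by the normalizer mean."""
    if norm_mean <= 0:
        raise ValueError("pausing index undefined for zero normalizer coverage")
    return track.mean_over(regions) / norm_mean


def track_gene_mean(track: CoverageTrack, genes: Iterable[GeneModel]) -> float:
    """Mean coverage over all annotated gene bodies (track normalizer)."""
    return track.mean_over([g.span for g in genes])


def gene_profile(track: CoverageTrack, gene: GeneModel, schema: RegionSchema,
                 normalization: str = "gene_body",
                 track_mean: Optional[float] = None) -> Optional[dict[str, float]]:
    """Per-region pausing indices for one gene; None if the gene is excluded
    (zero gene-body coverage under gene_body normalization)."""
    body_mean = track.mean(gene.span)
    if normalization == "gene_body":
        if body_mean == 0:
            return None
        norm = body_mean
    elif normalization == "track":
        if track_mean is None or track_mean <= 0:
            raise ValueError("track normalization requires a positive track_mean")
        norm = track_mean
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    out = {}
    for label, ivs in schema.regions.items():
        if ivs:
            out[label] = pausing_index(track, ivs, norm)
    return out


def metaprofile(cohort: Iterable[tuple[CircRNA, GeneModel]], track: CoverageTrack,
                flank: int = 300, normalization: str = "gene_body",
                track_mean: Optional[float] = None) -> pd.DataFrame:
    """Cohort-level pausing profile: per-region mean, SEM, n over genes."""
    per_gene = []
    for circ, gene in cohort:
        schema = define_regions(circ, gene, flank=flank)
        prof = gene_profile(track, gene, schema, normalization, track_mean)
        if prof is not None:
            prof["gene_id"] = gene.gene_id
            per_gene.append(prof)
    if not per_gene:
        raise ValueError("metaprofile needs at least one includable gene")
    df = pd.DataFrame(per_gene).set_index("gene_id")
    rows = []
    for label in df.columns:
        vals = df[label].dropna().to_numpy()
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows.append(
            {
                "region": label,
                "n": len(vals),
                "mean_index": float(vals.mean()),
                "sem": float(sd / math.sqrt(len(vals))) if len(vals) else np.nan,
            }
        )
    summary = pd.DataFrame(rows)
    summary.attrs["per_gene"] = df
    return summary


def compare_profiles(profile_a: pd.DataFrame, profile_b: pd.DataFrame) -> pd.DataFrame:
    """Welch test per shared region between two cohorts' per-gene indices."""
    a = profile_a.attrs["per_gene"]
    b = profile_b.attrs["per_gene"]
    rows = []
    for label in sorted(set(a.columns) & set(b.columns)):
        va, vb = a[label].dropna(), b[label].dropna()
        if len(va) > 1 and len(vb) > 1 and (va.std() > 0 or vb.std() > 0):
            p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
        else:
            p = np.nan
        rows.append({"region": label, "mean_a": va.mean(), "mean_b": vb.mean(), "p": p})
    return pd.DataFrame(rows)


def classify_change(delta: float, tau: float = DEFAULT_TAU) -> str:
    """Classify a log2 pausing change with a symmetric threshold."""
    if delta > tau:
        return INCREASED
    if delta < -tau:
        return DECREASED
    return NO_CHANGE


def delta_pausing(profile_ref: dict[str, float], profile_alt: dict[str, float],
                  tau: float = DEFAULT_TAU, eps: float = EPS) -> pd.DataFrame:
    """Per-region log2(alt/ref) pausing change with classes."""
    rows = []
    for label in profile_ref:
        if label not in profile_alt:
            continue
        delta = math.log2((profile_alt[label] + eps) / (profile_ref[label] + eps))
        rows.append({"region": label, "log2_delta": delta,
                     "change": classify_change(delta, tau)})
    return pd.DataFrame(rows)


def intron_exon_pausing(gene: GeneModel, track: CoverageTrack,
                        normalization: str = "gene_body",
                        track_mean: Optional[float] = None) -> dict:
    """Pooled exonic vs pooled intronic pausing indices for one gene."""
    body_mean = track.mean(gene.span)
    if normalization == "gene_body":
        if body_mean == 0:
            return {"gene_id": gene.gene_id, "excluded": True}
        norm = body_mean
    elif normalization == "track":
        if track_mean is None or track_mean <= 0:
            raise ValueError("track normalization requires a positive track_mean")
        norm = track_mean
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    out = {
        "gene_id": gene.gene_id,
        "excluded": False,
        "exon_index": pausing_index(track, gene.exons, norm),
    }
    introns = gene.introns
    if introns:
        out["intron_index"] = pausing_index(track, introns, norm)
        out["intron_defined"] = True
    else:
        out["intron_index"] = np.nan
        out["intron_defined"] = False
    return out


def intron_exon_delta_classes(genes: Iterable[GeneModel],
                              track_ref: CoverageTrack, track_alt: CoverageTrack,
                              norm_genes: Iterable[GeneModel],
                              tau: float = DEFAULT_TAU,
                              eps: float = EPS) -> pd.DataFrame:
    """Exon/intron pausing-change classes per gene between two conditions.

    Uses track normalization (mean over ``norm_genes`` bodies per track) so
    that absolute occupancy changes are visible in both compartments.
    """
    norm_genes = list(norm_genes)
    mean_ref = track_gene_mean(track_ref, norm_genes)
    mean_alt = track_gene_mean(track_alt, norm_genes)
    rows = []
    for gene in genes:
        a = intron_exon_pausing(gene, track_ref, "track", mean_ref)
        b = intron_exon_pausing(gene, track_alt, "track", mean_alt)
        if a.get("excluded") or b.get("excluded"):
            continue
        row = {"gene_id": gene.gene_id}
        d_ex = math.log2((b["exon_index"] + eps) / (a["exon_index"] + eps))
        row["exon_log2_delta"] = d_ex
        row["exon_change"] = classify_change(d_ex, tau)
        if a["intron_defined"] and b["intron_defined"]:
            d_in = math.log2((b["intron_index"] + eps) / (a["intron_index"] + eps))
            row["intron_log2_delta"] = d_in
            row["intron_change"] = classify_change(d_in, tau)
        else:
            row["intron_log2_delta"] = np.nan
            row["intron_change"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def class_percentages(classes: Iterable[str], decimals: int = 1) -> dict[str, float]:
    """Percentage of each pausing class, to one decimal by default."""
    classes = [c for c in classes if c]
    n = len(classes)
    out = {}
    for label in (INCREASED, DECREASED, NO_CHANGE):
        out[label] = round(100.0 * sum(c == label for c in classes) / n, decimals) if n else 0.0
    return out
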