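"""Host-gene architecture statistics.

Backsplicing favours long flanking introns: the intron immediately
transcript-5' of the acceptor exon (upstream) and immediately 3' of the
donor exon (downstream). This module extracts those flanks per exonic
circRNA, summarizes gene/intron/exon lengths against background genes,
and tests group differences. Flanks at gene termini are flagged as
undefined and excluded, never imputed.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import CircRNA
from .model import GeneModel, Interval


def flanking_introns(circ: CircRNA, gene: GeneModel) -> tuple[Optional[Interval], Optional[Interval]]:
    """(upstream, downstream) flanking introns in transcript orientation.

    ``None`` marks an undefined flank (acceptor is the first exon or the
    donor is the last). Strand-aware: for minus-strand genes the upstream
    intron has the larger genomic coordinates.
    """
    if not circ.is_exonic:
        raise ValueError("flanking-intron analysis applies to exonic circRNAs only")
    if circ.host_gene_id != gene.gene_id:
        raise ValueError(f"circRNA assigned to {circ.host_gene_id}, not {gene.gene_id}")
    acc, don = circ.acceptor_exon_index, circ.donor_exon_index
    introns = gene.introns
    upstream = introns[acc - 1] if acc > 0 else None
    downstream = introns[don] if don < gene.n_exons - 1 else None
    return upstream, downstream


def build_records(circs: Iterable[CircRNA], genes_by_id: dict[str, GeneModel]) -> pd.DataFrame:
    """One row per exonic circRNA with the Fig-style length categories."""
    rows = []
    for c in circs:
        if not c.is_exonic or c.host_gene_id not in genes_by_id:
            continue
        gene = genes_by_id[c.host_gene_id]
        up, dn = flanking_introns(c, gene)
        acc, don = c.acceptor_exon_index, c.donor_exon_index
        circ_exons = gene.exons[acc : don + 1]
        rows.append(
            {
                "host_gene_id": gene.gene_id,
                "condition": c.condition,
                "circ_class": c.circ_class,
                "gene_length": gene.length,
                "upstream_intron_length": up.length if up else np.nan,
                "downstream_intron_length": dn.length if dn else np.nan,
                "internal_intron_lengths": [iv.length for iv in c.internal_introns],
                "circ_exon_lengths": [e.length for e in circ_exons],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "host_gene_id", "condition", "circ_class", "gene_length",
            "upstream_intron_length", "downstream_intron_length",
            "internal_intron_lengths", "circ_exon_lengths",
        ],
    )


def _group_stats(values: Sequence[float]) -> dict:
    arr = np.asarray([v for v in values if not (isinstance(v, float) and math.isnan(v))], dtype=float)
    n = len(arr)
    if n == 0:
        return {"n": 0, "mean": np.nan, "median": np.nan, "sem": np.nan}
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    return {
        "n": n,
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "sem": sd / math.sqrt(n) if n > 0 else np.nan,
    }


def summarize(records: pd.DataFrame, background_genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Per-condition means/medians/SEM for each length class plus background.

    Background rows pool gene, intron, and exon lengths over all supplied
    non-host genes.
    """
    background_genes = list(background_genes)
    rows = []
    for cond, grp in records.groupby("condition", sort=True):
        internal = [x for lst in grp["internal_intron_lengths"] for x in lst]
        circ_exons = [x for lst in grp["circ_exon_lengths"] for x in lst]
        for label, values in (
            ("gene_length", grp["gene_length"].tolist()),
            ("upstream_intron", grp["upstream_intron_length"].tolist()),
            ("downstream_intron", grp["downstream_intron_length"].tolist()),
            ("internal_intron", internal),
            ("circ_exon", circ_exons),
        ):
            rows.append({"group": cond, "length_class": label, **_group_stats(values)})
    bg_gene = [g.length for g in background_genes]
    bg_intron = [iv.length for g in background_genes for iv in g.introns]
    bg_exon = [e.length for g in background_genes for e in g.exons]
    for label, values in (
        ("gene_length", bg_gene),
        ("intron", bg_intron),
        ("exon", bg_exon),
    ):
        rows.append({"group": "background", "length_class": label, **_group_stats(values)})
    return pd.DataFrame(rows, columns=["group", "length_class", "n", "mean", "median", "sem"])


def compare_lengths(group_a: Sequence[float], group_b: Sequence[float],
                    test: str = "welch-log") -> float:
    """Two-sided p for a difference in length distributions.

    ``welch-log`` (default): Welch's t on log-transformed lengths, suited to
    heavy-tailed intron lengths. ``student-raw``: Student's t on raw
    lengths, matching a plain t-test on reported means.
    """
    a = np.asarray([v for v in group_a if np.isfinite(v)], dtype=float)
    b = np.asarray([v for v in group_b if np.isfinite(v)], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("compare_lengths needs >= 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    if test == "welch-log":
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("log test requires positive lengths")
        res = stats.ttest_ind(np.log(a), np.log(b), equal_var=False)
    elif test == "student-raw":
        res = stats.ttest_ind(a, b, equal_var=True)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.pvalue)


def asymmetry(records: pd.DataFrame, paired: bool = True) -> dict:
    """Upstream/downstream flank asymmetry over records with both flanks.

    ratio = mean(up) / mean(down); p from a paired t on per-circRNA
    (up - down) differences by default (unpaired Welch optional).
    """
    both = records.dropna(subset=["upstream_intron_length", "downstream_intron_length"])
    if both.empty:
        raise ValueError("no records with both flanking introns defined")
    up = both["upstream_intron_length"].to_numpy(dtype=float)
    dn = both["downstream_intron_length"].to_numpy(dtype=float)
    out = {
        "n": len(both),
        "mean_up": float(up.mean()),
        "mean_down": float(dn.mean()),
        "ratio": float(up.mean() / dn.mean()),
    }
    if len(both) < 2:
        out["p"] = np.nan
        out["p_defined"] = False
        return out
    if paired:
        diff = up - dn
        if diff.std(ddof=1) == 0:
            out["p"] = 1.0 if diff.mean() == 0 else 0.0
        else:
            out["p"] = float(stats.ttest_rel(up, dn).pvalue)
    else:
        out["p"] = compare_lengths(up, dn, test="welch-log")
    out["p_defined"] = True
    return out
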