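"""Readers and writers for the formats the pipeline touches.

GTF (1-based inclusive on disk), FASTA, BED6, strand-pair bedGraph
(``<prefix>.plus.bedgraph`` / ``<prefix>.minus.bedgraph``) and a junction
TSV dialect (header: chrom, start, end, strand, circ_type, gene,
condition, n_reads; unknown extra columns are ignored). Everything is
0-based half-open in memory.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import GeneModel, Interval, JunctionCall, ParseError

JUNCTION_COLUMNS = ["chrom", "start", "end", "strand", "circ_type", "gene", "condition", "n_reads"]


# ---------------------------------------------------------------------------
# GTF


def _prevalidate_gtf(path: str) -> None:
    """Cheap line-level checks so errors can name a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            if fields[6] not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {fields[6]!r}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise ParseError(f"{path}:{lineno}: bad coordinates {start}-{end}")


def read_gtf(path: str) -> list[GeneModel]:
    """Parse a GTF into gene models, one representative transcript per gene.

    The representative transcript is the one with the longest genomic span;
    ties break to the lexicographically smallest transcript_id. GTF 1-based
    inclusive coordinates are converted to 0-based half-open.
    """
    _prevalidate_gtf(path)
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        verbose=False,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best = None
        for tx in db.children(gene, featuretype="transcript"):
            exons = [
                Interval(e.seqid, e.start - 1, e.end, e.strand)
                for e in db.children(tx, featuretype="exon")
            ]
            if not exons:
                continue
            lo = min(e.start for e in exons)
            hi = max(e.end for e in exons)
            if tx.start - 1 > lo or tx.end < hi:
                raise ParseError(
                    f"{path}: exon outside transcript span for transcript {tx.id}"
                )
            span = hi - lo
            key = (-span, tx.id)
            if best is None or key < best[0]:
                best = (key, tx.id, exons)
        if best is None:
            continue
        _, tx_id, exons = best
        genes.append(
            GeneModel(
                gene_id=gene.id,
                transcript_id=tx_id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=exons,
            )
        )
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str, source: str = "circarch") -> None:
    with open(path, "w") as fh:
        for g in genes:
            span = g.span
            attrs_gene = f'gene_id "{g.gene_id}";'
            attrs_tx = f'gene_id "{g.gene_id}"; transcript_id "{g.transcript_id}";'
            fh.write(
                "\t".join(
                    [g.chrom, source, "gene", str(span.start + 1), str(span.end), ".",
                     g.strand, ".", attrs_gene]
                )
                + "\n"
            )
            fh.write(
                "\t".join(
                    [g.chrom, source, "transcript", str(span.start + 1), str(span.end), ".",
                     g.strand, ".", attrs_tx]
                )
                + "\n"
            )
            for i, e in enumerate(g.exons_genomic, start=1):
                attrs_ex = attrs_tx + f' exon_number "{i}";'
                fh.write(
                    "\t".join(
                        [g.chrom, source, "exon", str(e.start + 1), str(e.end), ".",
                         g.strand, ".", attrs_ex]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str) -> pd.DataFrame:
    """BED6 (0-based half-open) with the repeat class in the name column."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "start": int, "end": int, "name": str},
    )
    if (df["start"] >= df["end"]).any():
        bad = df.index[(df["start"] >= df["end"])][0] + 1
        raise ParseError(f"{path}: malformed BED interval at data line {bad}")
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    out = df.copy()
    for c, default in (("name", "."), ("score", 0), ("strand", ".")):
        if c not in out:
            out[c] = default
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def bed_intervals(df: pd.DataFrame) -> list[Interval]:
    return [
        Interval(r.chrom, int(r.start), int(r.end), r.strand if r.strand in ("+", "-") else ".")
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Coverage / bedGraph


class CoverageTrack:
    """Strand-resolved per-base coverage; queries outside data return 0."""

    def __init__(self) -> None:
        self._data: dict[tuple[str, str], np.ndarray] = {}

    def set_array(self, chrom: str, strand: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if (values < 0).any():
            raise ValueError("coverage values must be >= 0")
        self._data[(chrom, strand)] = values

    def chroms(self) -> list[str]:
        return sorted({c for c, _ in self._data})

    def values(self, chrom: str, start: int, end: int, strand: str) -> np.ndarray:
        """Per-base values over [start, end); zero-padded outside coverage."""
        out = np.zeros(end - start, dtype=float)
        arr = self._data.get((chrom, strand))
        if arr is None:
            return out
        lo = max(start, 0)
        hi = min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def mean(self, interval: Interval) -> float:
        return float(
            self.values(interval.chrom, interval.start, interval.end, interval.strand).mean()
        )

    def mean_over(self, intervals: Iterable[Interval]) -> float:
        chunks = [self.values(iv.chrom, iv.start, iv.end, iv.strand) for iv in intervals]
        if not chunks:
            raise ValueError("mean_over needs at least one interval")
        return float(np.concatenate(chunks).mean())

    def scaled(self, factor: float) -> "CoverageTrack":
        out = CoverageTrack()
        for (chrom, strand), arr in self._data.items():
            out.set_array(chrom, strand, arr * factor)
        return out


def _runs(arr: np.ndarray):
    """Yield (start, end, value) runs of constant nonzero value."""
    if len(arr) == 0:
        return
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(arr)]))
    for s, e in zip(starts, ends):
        v = arr[s]
        if v != 0:
            yield int(s), int(e), float(v)


def write_bedgraph_pair(track: CoverageTrack, prefix: str) -> tuple[str, str]:
    """Write ``<prefix>.plus.bedgraph`` / ``<prefix>.minus.bedgraph``."""
    paths = []
    for strand, suffix in (("+", "plus"), ("-", "minus")):
        path = f"{prefix}.{suffix}.bedgraph"
        with open(path, "w") as fh:
            for chrom in track.chroms():
                arr = track._data.get((chrom, strand))
                if arr is None:
                    continue
                for s, e, v in _runs(arr):
                    val = f"{int(v)}" if float(v).is_integer() else f"{v:g}"
                    fh.write(f"{chrom}\t{s}\t{e}\t{val}\n")
        paths.append(path)
    return tuple(paths)


def read_bedgraph_pair(plus_path: str, minus_path: str) -> CoverageTrack:
    track = CoverageTrack()
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        if os.path.getsize(path) > 0:
            df = pd.read_csv(
                path, sep="\t", header=None, comment="#",
                names=["chrom", "start", "end", "value"],
                dtype={"chrom": str, "start": int, "end": int, "value": float},
            )
            for r in df.itertuples():
                if r.start >= r.end:
                    raise ParseError(f"{path}: malformed bedGraph interval {r.start}-{r.end}")
                per_chrom.setdefault(r.chrom, []).append((r.start, r.end, r.value))
        for chrom, rows in per_chrom.items():
            rows.sort()
            for (s1, e1, _), (s2, _, _) in zip(rows, rows[1:]):
                if s2 < e1:
                    raise ParseError(f"{path}: overlapping bedGraph intervals on {chrom}")
            arr = np.zeros(rows[-1][1], dtype=float)
            for s, e, v in rows:
                arr[s:e] = v
            track.set_array(chrom, strand, arr)
    return track


# ---------------------------------------------------------------------------
# Junction TSV


def read_junctions(path: str) -> list[JunctionCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "start", "end", "strand", "condition"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing junction columns {sorted(missing)}")
    calls = []
    for i, r in enumerate(df.itertuples(), start=2):
        if int(r.start) >= int(r.end):
            raise ParseError(f"{path}:{i}: junction start must be < end (acceptor/donor order)")
        n_reads = getattr(r, "n_reads", None)
        if n_reads is not None and not pd.isna(n_reads):
            n_reads = int(n_reads)
        else:
            n_reads = None
        gene = getattr(r, "gene", None)
        calls.append(
            JunctionCall(
                chrom=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                strand=str(r.strand),
                condition=str(r.condition),
                gene_hint=None if gene is None or pd.isna(gene) else str(gene),
                n_reads=n_reads,
            )
        )
    return calls


def write_junctions(calls: Iterable[JunctionCall], path: str,
                    circ_types: Optional[Iterable[str]] = None) -> None:
    rows = []
    types = list(circ_types) if circ_types is not None else None
    for i, c in enumerate(calls):
        rows.append(
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "circ_type": types[i] if types else "",
                "gene": c.gene_hint or "",
                "condition": c.condition,
                "n_reads": "" if c.n_reads is None else c.n_reads,
            }
        )
    pd.DataFrame(rows, columns=JUNCTION_COLUMNS).to_csv(path, sep="\t", index=False)
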