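"""Core coordinate data model.

All coordinates are 0-based half-open internally; GTF is the only 1-based
surface (handled by :mod:`circarch.genomeio`). Gene models keep exons in
transcript (5'->3') orientation, so for minus-strand genes the first exon
has the largest genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

STRANDS = ("+", "-", ".")


class CircArchError(Exception):
    """Base class for package errors."""


class ConfigError(CircArchError):
    """Invalid or infeasible configuration."""


class ParseError(CircArchError):
    """Malformed input file."""


@dataclass(frozen=True, order=True)
class Interval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def shift(self, offset: int) -> "Interval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass
class GeneModel:
    """A gene with one representative transcript.

    ``exons`` are ordered in transcript orientation; ``introns`` are the
    gaps between adjacent exons, also in transcript orientation.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: needs at least one exon")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.gene_id}: overlapping exons {a} / {b}")
        # normalize ordering to transcript orientation
        self.exons = genomic if self.strand == "+" else genomic[::-1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exons_genomic(self) -> list[Interval]:
        return sorted(self.exons, key=lambda e: e.start)

    @property
    def introns(self) -> list[Interval]:
        """Introns in transcript orientation."""
        out = []
        for up, dn in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append(Interval(self.chrom, up.end, dn.start, self.strand))
            else:
                out.append(Interval(self.chrom, dn.end, up.start, self.strand))
        return out

    @property
    def span(self) -> Interval:
        g = self.exons_genomic
        return Interval(self.chrom, g[0].start, g[-1].end, self.strand)

    @property
    def length(self) -> int:
        return self.span.length

    def exon_index_genomic_start(self, pos: int, tol: int = 0) -> Optional[int]:
        """Transcript-orientation index of the exon whose genomic start is ``pos``."""
        for i, e in enumerate(self.exons):
            if abs(e.start - pos) <= tol:
                return i
        return None

    def exon_index_genomic_end(self, pos: int, tol: int = 0) -> Optional[int]:
        for i, e in enumerate(self.exons):
            if abs(e.end - pos) <= tol:
                return i
        return None


@dataclass(frozen=True)
class JunctionCall:
    """A backsplice junction call.

    ``start``/``end`` delimit the genomic span of the circle (0-based
    half-open, start < end). On '+' genes the acceptor (transcript-5')
    boundary is ``start`` and the donor boundary is ``end``; on '-' genes
    the roles are mirrored.
    """

    chrom: str
    start: int
    end: int
    strand: str
    condition: str = ""
    gene_hint: Optional[str] = None
    n_reads: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"junction {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"junction strand must be + or -, got {self.strand!r}")

    @property
    def identity(self) -> tuple:
        """Condition-independent junction identity."""
        return (self.chrom, self.start, self.end, self.strand)


def junctions_equal(a: JunctionCall, b: JunctionCall) -> bool:
    return a.identity == b.identity


def total_span(intervals: Sequence[Interval]) -> int:
    return sum(iv.length for iv in intervals)
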