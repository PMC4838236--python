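"""Core genomic data types and interval arithmetic.

All coordinates are 0-based, half-open (BED native): an interval [start, end)
covers positions start .. end-1, and a point insertion at position p occupies
the single base [p, p+1). This convention is used end to end; every writer
states it in its output header.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence


class GripError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(GripError):
    """A malformed input file; the message names the offending line."""


class DomainError(GripError, ValueError):
    """Arguments outside the domain of an operation."""


class Strand(enum.Enum):
    """Orientation of a feature or provirus on the reference genome."""

    FORWARD = "+"
    REVERSE = "-"

    @classmethod
    def parse(cls, token: str) -> "Strand":
        if token == "+":
            return cls.FORWARD
        if token == "-":
            return cls.REVERSE
        raise ParseError(f"invalid strand token {token!r}: expected '+' or '-'")

    def flipped(self) -> "Strand":
        return Strand.REVERSE if self is Strand.FORWARD else Strand.FORWARD

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise DomainError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise DomainError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class InsertionSite:
    """A strand-oriented proviral integration point.

    ``copies`` is the number of junction fragments supporting this unique
    insertion — the clonal copy count. Identity is (chrom, pos, strand);
    duplicate records on ingest are merged by summing copies.
    """

    chrom: str
    pos: int
    strand: Strand
    copies: int = 1
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise DomainError(f"negative insertion position {self.pos}")
        if self.copies < 1:
            raise DomainError(f"copies must be >= 1, got {self.copies}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.strand)


def merge_insertions(sites: Iterable[InsertionSite]) -> list[InsertionSite]:
    """Merge insertions sharing (chrom, pos, strand), summing copies.

    Returns a list sorted by (chrom, pos, strand); the first-seen id wins.
    """
    merged: dict[tuple, InsertionSite] = {}
    for s in sites:
        prev = merged.get(s.key)
        if prev is None:
            merged[s.key] = s
        else:
            merged[s.key] = InsertionSite(
                s.chrom, s.pos, s.strand, prev.copies + s.copies, prev.id
            )
    return sorted(merged.values(), key=lambda s: (s.chrom, s.pos, s.strand.value))


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand; the TSS is derived from the strand.

    For a forward gene the TSS is tx_start; for a reverse gene it is
    tx_end - 1 (the last covered base, 0-based).
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: Strand
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.tx_start < 0:
            raise DomainError(f"{self.gene_id}: negative tx_start")
        if self.tx_start >= self.tx_end:
            raise DomainError(
                f"{self.gene_id}: tx_start {self.tx_start} >= tx_end {self.tx_end}"
            )

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand is Strand.FORWARD else self.tx_end - 1

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end)

    def window(self, flank: int = 25000) -> "GeneWindow":
        return GeneWindow(self, flank)

    def body_distance(self, pos: int) -> int:
        """Distance in bp from a point to the nearest covered base (0 inside)."""
        if pos < self.tx_start:
            return self.tx_start - pos
        if pos >= self.tx_end:
            return pos - (self.tx_end - 1)
        return 0


@dataclass(frozen=True)
class GeneWindow:
    """A gene span extended by ``flank`` bp on both sides.

    The left edge truncates at position 0; chromosome right ends are unknown
    to the gene table, so there is no right truncation.
    """

    gene: GeneModel
    flank: int = 25000

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise DomainError(f"negative flank {self.flank}")

    @property
    def interval(self) -> GenomicInterval:
        g = self.gene
        return GenomicInterval(
            g.chrom, max(0, g.tx_start - self.flank), g.tx_end + self.flank
        )

    @property
    def length(self) -> int:
        return self.interval.length

    def contains(self, chrom: str, pos: int) -> bool:
        return self.interval.contains(chrom, pos)


@dataclass
class Peak:
    interval: GenomicInterval
    score: Optional[float] = None
    name: Optional[str] = None


@dataclass
class PeakCollection:
    """A named set of intervals for one chromatin mark (e.g. H3K27ac)."""

    mark_name: str
    peaks: list[Peak] = field(default_factory=list)
    source_dialect: str = "bed"

    def __post_init__(self) -> None:
        self.peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
        for p in self.peaks:
            if p.score is not None and not (p.score == p.score and abs(p.score) != float("inf")):
                raise DomainError(f"{self.mark_name}: non-finite peak score")

    def __len__(self) -> int:
        return len(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


@dataclass
class RankedGeneList:
    """Gene symbols ordered by descending numeric score; ties allowed."""

    symbols: list[str]
    scores: list[float]

    def __post_init__(self) -> None:
        if len(self.symbols) != len(self.scores):
            raise DomainError("symbols and scores must have equal length")
        if len(set(self.symbols)) != len(self.symbols):
            dupes = sorted({s for s in self.symbols if self.symbols.count(s) > 1})
            raise DomainError(f"duplicate symbols in ranked list: {dupes[:5]}")
        order = sorted(range(len(self.scores)), key=lambda i: -self.scores[i])
        self.symbols = [self.symbols[i] for i in order]
        self.scores = [self.scores[i] for i in order]

    def __len__(self) -> int:
        return len(self.symbols)

    def top(self, size: int, expand_ties: bool = True) -> list[str]:
        """The top ``size`` symbols, optionally expanded across the boundary tie.

        With ``expand_ties`` every symbol whose score equals the score at rank
        ``size`` is included, so the effective size may exceed ``size``.
        """
        if size < 1:
            raise DomainError(f"size must be >= 1, got {size}")
        if size >= len(self.symbols):
            return list(self.symbols)
        if not expand_ties:
            return self.symbols[:size]
        cutoff = self.scores[size - 1]
        n = size
        while n < len(self.symbols) and self.scores[n] == cutoff:
            n += 1
        return self.symbols[:n]


@dataclass
class GeneSet:
    """An annotated set of gene symbols (e.g. cancer drivers).

    ``background_fraction`` is the proportion of all genes carrying the
    annotation, used as the null rate in enrichment tests.
    """

    name: str
    symbols: set[str]
    background_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.background_fraction is not None and not (
            0 < self.background_fraction < 1
        ):
            raise DomainError(
                f"background_fraction must lie in (0,1), got {self.background_fraction}"
            )
        self.symbols = {s.upper() for s in self.symbols}

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


def union_length(intervals: Sequence[GenomicInterval]) -> int:
    """Total bp covered by the union of intervals; overlaps counted once."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    total = 0
    for spans in by_chrom.values():
        spans.sort()
        cur_start, cur_end = spans[0]
        for s, e in spans[1:]:
            if s > cur_end:
                total += cur_end - cur_start
                cur_start, cur_end = s, e
            else:
                cur_end = max(cur_end, e)
        total += cur_end - cur_start
    return total


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """The union of intervals as a sorted list of disjoint intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_start, cur_end = spans[0]
        for s, e in spans[1:]:
            if s > cur_end:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = s, e
            else:
                cur_end = max(cur_end, e)
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out
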