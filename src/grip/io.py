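"""Readers and writers for the external text formats.

Inputs: BED3/BED6 insertion files, refFlat-like gene tables, ENCODE
narrowPeak (10 columns) / broadPeak (9 columns) peak files, two-column
ranked gene lists, and one-symbol-per-line gene sets. Outputs are TSV with
'#'-prefixed header lines. All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .core import (
    GeneModel,
    GeneSet,
    GenomicInterval,
    InsertionSite,
    ParseError,
    Peak,
    PeakCollection,
    RankedGeneList,
    Strand,
    merge_insertions,
)

PathLike = Union[str, Path]


@dataclass
class LoadReport:
    """Ingest accounting: lines seen, records kept, merges, rejects."""

    n_lines: int = 0
    n_records: int = 0
    n_merged: int = 0
    n_rejected: int = 0
    n_defaulted_strand: int = 0
    warnings: list[str] = field(default_factory=list)


def _data_lines(path: PathLike):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_insertions_bed(
    path: PathLike,
    copies_field: Optional[Union[int, str]] = "score",
    strict: bool = True,
) -> tuple[list[InsertionSite], LoadReport]:
    """Read unique insertion sites from a BED3/BED6 file.

    The integration point is the BED start coordinate; the end field is only
    validated (end == start + 1 expected, a warning is recorded otherwise).
    ``copies_field`` selects the column carrying the junction-fragment count:
    ``"score"`` for BED column 5, a 0-based column index, or None for
    copies = 1 everywhere. Non-positive or non-numeric values in that column
    fall back to 1. Records sharing (chrom, pos, strand) are merged by
    summing copies.

    In ``strict`` mode a '.' or missing strand raises ParseError; in lenient
    mode such records default to forward strand and are counted in the
    report.
    """
    if copies_field == "score":
        copies_col: Optional[int] = 4
    else:
        copies_col = copies_field  # type: ignore[assignment]
    report = LoadReport()
    raw_sites: list[InsertionSite] = []
    for lineno, fields in _data_lines(path):
        report.n_lines += 1
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
        chrom = fields[0]
        try:
            start = int(fields[1])
            end = int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        if start < 0:
            raise ParseError(f"{path}:{lineno}: negative start {start}")
        if end != start + 1 and not report.warnings:
            report.warnings.append(
                f"line {lineno}: end != start + 1; the start coordinate is "
                "used as the integration point"
            )
        name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else None
        strand_token = fields[5] if len(fields) > 5 else "."
        if strand_token in ("+", "-"):
            strand = Strand.parse(strand_token)
        elif strict:
            raise ParseError(
                f"{path}:{lineno}: strand {strand_token!r} not '+'/'-' "
                "(use strict=False to default to forward)"
            )
        else:
            strand = Strand.FORWARD
            report.n_defaulted_strand += 1
        copies = 1
        if copies_col is not None and len(fields) > copies_col:
            try:
                value = float(fields[copies_col])
                if value >= 1:
                    copies = int(round(value))
            except ValueError:
                pass
        raw_sites.append(InsertionSite(chrom, start, strand, copies, name))
    merged = merge_insertions(raw_sites)
    report.n_records = len(merged)
    report.n_merged = len(raw_sites) - len(merged)
    return merged, report


def write_insertions_bed(
    path: PathLike, insertions: Sequence[InsertionSite], header: Sequence[str] = ()
) -> None:
    """Write insertions as BED6 (score column = copies); round-trips exactly."""
    with open(path, "w") as fh:
        fh.write("# insertion sites, 0-based half-open; score column = copies\n")
        for line in header:
            fh.write(f"# {line}\n")
        for s in insertions:
            name = s.id if s.id is not None else "."
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{name}\t{s.copies}\t{s.strand}\n")


def read_gene_table(path: PathLike) -> tuple[list[GeneModel], LoadReport]:
    """Read a refFlat-style gene table.

    Columns (tab-separated, >= 6): gene_id, symbol, chrom, strand, txStart,
    txEnd. Rows with txStart >= txEnd are rejected and counted in the report;
    duplicate gene ids raise ParseError.
    """
    report = LoadReport()
    genes: list[GeneModel] = []
    seen: dict[str, int] = {}
    for lineno, fields in _data_lines(path):
        report.n_lines += 1
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: expected >= 6 columns")
        gene_id, symbol, chrom, strand_token = fields[:4]
        try:
            tx_start, tx_end = int(fields[4]), int(fields[5])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        strand = Strand.parse(strand_token)
        if gene_id in seen:
            raise ParseError(
                f"{path}:{lineno}: duplicate gene id {gene_id!r} "
                f"(first seen on line {seen[gene_id]})"
            )
        seen[gene_id] = lineno
        if tx_start >= tx_end:
            report.n_rejected += 1
            report.warnings.append(
                f"line {lineno}: rejected {gene_id}: txStart >= txEnd"
            )
            continue
        genes.append(GeneModel(gene_id, symbol, chrom, strand, tx_start, tx_end))
    report.n_records = len(genes)
    return genes, report


def write_gene_table(path: PathLike, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_id\tsymbol\tchrom\tstrand\ttxStart\ttxEnd (0-based half-open)\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.symbol}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\n"
            )


_DIALECT_COLUMNS = {"narrowPeak": 10, "broadPeak": 9}


def read_peaks(path: PathLike, dialect: str = "narrowPeak", mark_name: Optional[str] = None) -> PeakCollection:
    """Read an ENCODE narrowPeak/broadPeak or plain BED peak file.

    narrowPeak requires exactly 10 columns (the summit column is parsed but
    unused), broadPeak exactly 9; ``bed`` accepts 3-6. The score column
    (column 5) is retained when present.
    """
    if dialect not in ("narrowPeak", "broadPeak", "bed"):
        raise ParseError(f"unknown peak dialect {dialect!r}")
    peaks: list[Peak] = []
    for lineno, fields in _data_lines(path):
        n = len(fields)
        if dialect in _DIALECT_COLUMNS:
            if n != _DIALECT_COLUMNS[dialect]:
                raise ParseError(
                    f"{path}:{lineno}: {dialect} requires "
                    f"{_DIALECT_COLUMNS[dialect]} columns, found {n}"
                )
        elif not 3 <= n <= 6:
            raise ParseError(f"{path}:{lineno}: BED requires 3-6 columns, found {n}")
        try:
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad interval") from exc
        score = None
        if n > 4:
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
        name = fields[3] if n > 3 and fields[3] != "." else None
        peaks.append(Peak(iv, score, name))
    if mark_name is None:
        mark_name = Path(path).stem
    return PeakCollection(mark_name, peaks, source_dialect=dialect)


def write_peaks_narrowpeak(path: PathLike, collection: PeakCollection) -> None:
    with open(path, "w") as fh:
        for p in collection.peaks:
            iv = p.interval
            name = p.name or "."
            score = int(p.score) if p.score is not None else 0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\t0\t-1\t-1\t-1\n"
            )


def read_ranked_list(path: PathLike) -> RankedGeneList:
    """Read a two-column (gene, score) TSV into a RankedGeneList."""
    symbols: list[str] = []
    scores: list[float] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns (gene, score)")
        symbols.append(fields[0])
        try:
            scores.append(float(fields[1]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
    return RankedGeneList(symbols, scores)


def read_gene_set(
    path: PathLike,
    name: Optional[str] = None,
    background_fraction: Optional[float] = None,
) -> GeneSet:
    """Read a gene set: one symbol per line, '#' comments allowed."""
    symbols: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            symbols.add(line.split("\t")[0])
    return GeneSet(name or Path(path).stem, symbols, background_fraction)


def write_tsv(path: PathLike, df, header_lines: Sequence[str] = ()) -> None:
    """Write a DataFrame as TSV with '#'-prefixed provenance header lines."""
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based half-open\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
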