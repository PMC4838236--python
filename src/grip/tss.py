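"""Strand-aware profiling of insertions around transcription start sites.

Gamma-retroviral insertions cluster in a double peak flanking the TSS with a
trough at the TSS itself. Distances here are signed in the gene's reading
direction: negative = upstream of the TSS, positive = downstream, so the
profile is comparable across strands. Position classes relative to the
nearest gene use the six-term vocabulary common in peak-annotation tools
(inside, upstream, downstream, overlapStart, overlapEnd, includeFeature);
a point insertion can only be inside, upstream or downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .core import DomainError, GeneModel, GenomicInterval, InsertionSite, Strand


@dataclass
class TssDistance:
    insertion_id: str
    gene_id: str
    distance: int  # signed, strand-relative bp; negative = upstream


class PositionClass(enum.Enum):
    INSIDE = "inside"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    OVERLAP_START = "overlapStart"
    OVERLAP_END = "overlapEnd"
    INCLUDE_FEATURE = "includeFeature"


class TssIndex:
    """Sorted per-chromosome index of TSS positions for nearest-TSS queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        if not genes:
            raise DomainError("gene set must be non-empty")
        self._by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.tss, g.gene_id))
            self._by_chrom[chrom] = (np.array([g.tss for g in gs]), gs)

    def nearest(self, chrom: str, pos: int) -> GeneModel | None:
        """Nearest gene by |pos - tss| on the same chromosome; ties by gene_id."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        positions, gs = entry
        i = int(np.searchsorted(positions, pos))
        candidates = [gs[j] for j in (i - 1, i, i + 1) if 0 <= j < len(gs)]
        return min(candidates, key=lambda g: (abs(pos - g.tss), g.gene_id))


def distance_to_nearest_tss(
    insertion: InsertionSite, tss_index: TssIndex
) -> TssDistance | None:
    """Signed strand-relative distance to the nearest TSS.

    Returns None when the insertion's chromosome carries no gene. The sign is
    flipped for reverse-strand genes so that "upstream of the TSS" is always
    negative in the gene's reading direction.
    """
    gene = tss_index.nearest(insertion.chrom, insertion.pos)
    if gene is None:
        return None
    offset = insertion.pos - gene.tss
    if gene.strand is Strand.REVERSE:
        offset = -offset
    ins_id = insertion.id or f"{insertion.chrom}:{insertion.pos}:{insertion.strand}"
    return TssDistance(ins_id, gene.gene_id, offset)


def tss_distances(
    insertions: Sequence[InsertionSite], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Per-insertion nearest-TSS distances and position classes."""
    index = TssIndex(genes)
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for ins in insertions:
        d = distance_to_nearest_tss(ins, index)
        if d is None:
            continue
        rows.append(
            {
                "insertion_id": d.insertion_id,
                "gene_id": d.gene_id,
                "distance": d.distance,
                "position_class": classify_position(ins, by_id[d.gene_id]).value,
            }
        )
    return pd.DataFrame(
        rows, columns=["insertion_id", "gene_id", "distance", "position_class"]
    )


def tss_histogram(
    distances: Sequence[int],
    bin_width: int = 500,
    hist_range: int = 10000,
) -> pd.DataFrame:
    """Histogram of signed TSS distances over [-hist_range, +hist_range).

    Half-open bins of ``bin_width`` bp; an ``out_of_range`` attribute on the
    returned frame counts insertions outside the range, so bin counts plus
    out-of-range equals the total.
    """
    if bin_width <= 0:
        raise DomainError(f"bin_width must be positive, got {bin_width}")
    if hist_range <= 0 or hist_range % bin_width:
        raise DomainError("hist_range must be a positive multiple of bin_width")
    edges = np.arange(-hist_range, hist_range + bin_width, bin_width)
    d = np.asarray(distances, dtype=float)
    in_range = (d >= -hist_range) & (d < hist_range)
    counts, _ = np.histogram(d[in_range], bins=edges)
    df = pd.DataFrame(
        {"bin_start": edges[:-1].astype(int), "bin_end": edges[1:].astype(int), "count": counts}
    )
    df.attrs["out_of_range"] = int((~in_range).sum())
    return df


def classify_position(
    feature: Union[InsertionSite, GenomicInterval], gene: GeneModel
) -> PositionClass:
    """Classify a point or interval relative to its assigned gene.

    Boundary classes are strand-relative: overlapStart means the interval
    spans the gene's 5' (TSS-side) boundary. Intervals containing the whole
    gene body are includeFeature.
    """
    if isinstance(feature, InsertionSite):
        start, end = feature.pos, feature.pos + 1
    else:
        if feature.chrom != gene.chrom:
            raise DomainError("feature and gene are on different chromosomes")
        start, end = feature.start, feature.end
    g_start, g_end = gene.tx_start, gene.tx_end
    if start <= g_start and end >= g_end:
        return PositionClass.INCLUDE_FEATURE
    spans_left = start < g_start < end
    spans_right = start < g_end < end
    if spans_left:
        return (
            PositionClass.OVERLAP_START
            if gene.strand is Strand.FORWARD
            else PositionClass.OVERLAP_END
        )
    if spans_right:
        return (
            PositionClass.OVERLAP_END
            if gene.strand is Strand.FORWARD
            else PositionClass.OVERLAP_START
        )
    if g_start <= start and end <= g_end:
        return PositionClass.INSIDE
    # wholly outside the body: upstream/downstream in reading direction
    left_of_gene = end <= g_start
    if gene.strand is Strand.FORWARD:
        return PositionClass.UPSTREAM if left_of_gene else PositionClass.DOWNSTREAM
    return PositionClass.DOWNSTREAM if left_of_gene else PositionClass.UPSTREAM
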