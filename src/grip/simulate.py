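"""Seeded generator of toy genomes, peak sets and insertion datasets.

The generator emulates the statistical structure of a gamma-retroviral
integration screen at desk scale: a multi-chromosome genome with
non-overlapping genes; chromatin-mark peaks at a subset of TSSs; insertions
drawn from a mixture of uniform background and peak/TSS-biased placement
with a symmetric double-peak offset around the TSS (a trough at the TSS is
produced by an exclusion zone around 0); geometric clonal copy counts; and
configurable orientation bias and targeting weight at designated genes.

All randomness flows from a single seed through named substreams (one per
stage), so any stage can be regenerated independently:
``default_rng([seed, stage])`` with stage 0 = genome, 1 = peaks,
2 = insertions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    DomainError,
    GeneModel,
    GenomicInterval,
    InsertionSite,
    Peak,
    PeakCollection,
    Strand,
    merge_insertions,
)


@dataclass
class SimulationConfig:
    """All generator knobs.

    The defaults describe a screen of 5,000 insertions on a 4 x 2 Mb toy
    genome with 200 genes, 60% chromatin-biased placement, a double-peak
    offset at +/-1.5 kb around the TSS, and a clonal copy distribution with
    mean ~2.6 copies per insertion.
    """

    n_chroms: int = 4
    chrom_length: int = 2_000_000
    n_genes: int = 200
    gene_length_min: int = 5_000
    gene_length_max: int = 20_000
    flank: int = 25_000
    pi: float = 0.6  # probability an insertion is chromatin-biased
    peak_fraction: float = 0.3  # fraction of TSSs carrying a peak
    peak_width: int = 2_000
    tss_offset_mode: int = 1_500  # bp, mode of the |offset| distribution
    tss_offset_sd: int = 600
    tss_offset_min: int = 300  # exclusion zone around the TSS
    hot_genes: dict = field(default_factory=dict)  # gene_id -> weight >= 1
    beta: float = 0.5  # default forward-orientation probability
    beta_overrides: dict = field(default_factory=dict)  # gene_id -> beta
    copies_geometric_p: float = 0.39  # copies ~ Geometric(p) on {1,2,...}
    n_insertions: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pi", "peak_fraction", "beta", "copies_geometric_p"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DomainError(f"{name} must lie in [0, 1], got {v}")
        if not 0 < self.copies_geometric_p:
            raise DomainError("copies_geometric_p must be positive")
        for name in ("chrom_length", "gene_length_min", "gene_length_max", "peak_width"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.gene_length_min > self.gene_length_max:
            raise DomainError("gene_length_min exceeds gene_length_max")
        for gid, w in self.hot_genes.items():
            if w < 1:
                raise DomainError(f"hot gene {gid} has weight {w} < 1")
        for gid, b in self.beta_overrides.items():
            if not 0 <= b <= 1:
                raise DomainError(f"beta override for {gid} outside [0, 1]")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def simulate_genome(config: SimulationConfig) -> list[GeneModel]:
    """Place non-overlapping genes with random gaps; strands Bernoulli(0.5).

    Genes are spread as evenly as possible across chromosomes; per
    chromosome, drawn lengths plus multinomially distributed gaps tile the
    chromosome, which guarantees disjoint placement. Raises DomainError if
    the genes cannot fit.
    """
    rng = config.rng(0)
    genes: list[GeneModel] = []
    counts = [
        config.n_genes // config.n_chroms
        + (1 if i < config.n_genes % config.n_chroms else 0)
        for i in range(config.n_chroms)
    ]
    gene_no = 0
    for ci, n_c in enumerate(counts):
        if n_c == 0:
            continue
        lengths = rng.integers(
            config.gene_length_min, config.gene_length_max + 1, size=n_c
        )
        slack = config.chrom_length - int(lengths.sum())
        if slack < 0:
            raise DomainError(
                f"cannot pack {n_c} genes of total length {lengths.sum()} "
                f"into a {config.chrom_length} bp chromosome"
            )
        gaps = rng.multinomial(slack, np.full(n_c + 1, 1.0 / (n_c + 1)))
        pos = 0
        for j in range(n_c):
            pos += int(gaps[j])
            start, end = pos, pos + int(lengths[j])
            strand = Strand.FORWARD if rng.random() < 0.5 else Strand.REVERSE
            genes.append(
                GeneModel(
                    gene_id=f"g{gene_no:04d}",
                    symbol=f"GENE{gene_no:04d}",
                    chrom=_chrom_name(ci),
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                )
            )
            pos = end
            gene_no += 1
    return genes


def simulate_peaks(
    genes: Sequence[GeneModel], config: SimulationConfig, mark_name: str = "simH3K27ac"
) -> PeakCollection:
    """A peak of ``peak_width`` bp centred at a Bernoulli-selected subset of TSSs.

    Designated hot genes always carry a peak so their targeting weight can
    act. Peak names record the gene id they are centred on.
    """
    rng = config.rng(1)
    peaks: list[Peak] = []
    for g in genes:
        selected = rng.random() < config.peak_fraction or g.gene_id in config.hot_genes
        if not selected:
            continue
        half = config.peak_width // 2
        start = max(0, g.tss - half)
        end = min(config.chrom_length, g.tss + config.peak_width - half)
        peaks.append(Peak(GenomicInterval(g.chrom, start, end), score=1000.0, name=g.gene_id))
    return PeakCollection(mark_name, peaks, source_dialect="narrowPeak")


def _draw_offsets(
    rng: np.random.Generator, n: int, mode: int, sd: int, min_offset: int
) -> np.ndarray:
    """|offset| from Normal(mode, sd), rejected below the exclusion zone."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = np.abs(rng.normal(mode, sd, size=(n - filled) * 2))
        draw = draw[draw >= min_offset][: n - filled]
        out[filled : filled + draw.size] = draw
        filled += draw.size
    return out


def simulate_insertions(
    genes: Sequence[GeneModel],
    peaks: PeakCollection,
    config: SimulationConfig,
) -> tuple[list[InsertionSite], pd.DataFrame]:
    """Draw insertions from the background/biased mixture.

    Each insertion: with probability ``pi`` a peak-bearing gene is chosen
    (hot-gene weights multiply its selection probability) and the insertion
    is placed at TSS +/- offset in the gene's reading direction, with the
    offset magnitude drawn from Normal(tss_offset_mode, tss_offset_sd)
    truncated below tss_offset_min — the double-peak/trough shape; otherwise
    the position is uniform over the genome. Strand is forward with
    probability beta(gene) (the default beta for background insertions);
    copies are Geometric(copies_geometric_p) on {1, 2, ...}.

    Returns the merged unique insertions plus a per-draw truth table with
    columns id, chrom, pos, strand, channel, gene_id, copies.
    """
    rng = config.rng(2)
    peak_gene_ids = [p.name for p in peaks.peaks if p.name is not None]
    by_id = {g.gene_id: g for g in genes}
    peak_genes = [by_id[gid] for gid in peak_gene_ids if gid in by_id]
    if config.pi > 0 and not peak_genes:
        raise DomainError("pi > 0 requires at least one peak-bearing gene")
    n = config.n_insertions
    biased = rng.random(n) < config.pi
    n_biased = int(biased.sum())

    chroms = np.empty(n, dtype=object)
    positions = np.empty(n, dtype=np.int64)
    strands = np.empty(n, dtype=object)
    gene_ids = np.empty(n, dtype=object)
    gene_ids[:] = ""

    if n_biased:
        weights = np.array(
            [float(config.hot_genes.get(g.gene_id, 1.0)) for g in peak_genes]
        )
        weights /= weights.sum()
        choice = rng.choice(len(peak_genes), size=n_biased, p=weights)
        offsets = _draw_offsets(
            rng, n_biased, config.tss_offset_mode, config.tss_offset_sd,
            config.tss_offset_min,
        )
        signs = np.where(rng.random(n_biased) < 0.5, 1, -1)
        idx = np.flatnonzero(biased)
        for row, gi, off, sign in zip(idx, choice, offsets, signs):
            g = peak_genes[gi]
            direction = sign if g.strand is Strand.FORWARD else -sign
            pos = int(np.clip(g.tss + direction * int(round(off)), 0, config.chrom_length - 1))
            chroms[row] = g.chrom
            positions[row] = pos
            gene_ids[row] = g.gene_id
            b = config.beta_overrides.get(g.gene_id, config.beta)
            strands[row] = "+" if rng.random() < b else "-"

    n_bg = n - n_biased
    if n_bg:
        idx = np.flatnonzero(~biased)
        flat = rng.integers(0, config.n_chroms * config.chrom_length, size=n_bg)
        for row, f in zip(idx, flat):
            chroms[row] = _chrom_name(int(f // config.chrom_length))
            positions[row] = int(f % config.chrom_length)
            strands[row] = "+" if rng.random() < config.beta else "-"

    copies = rng.geometric(config.copies_geometric_p, size=n)
    truth = pd.DataFrame(
        {
            "id": [f"ins{i:05d}" for i in range(n)],
            "chrom": chroms,
            "pos": positions,
            "strand": strands,
            "channel": np.where(biased, "biased", "background"),
            "gene_id": gene_ids,
            "copies": copies,
        }
    )
    sites = [
        InsertionSite(
            row.chrom, int(row.pos), Strand.parse(row.strand), int(row.copies), row.id
        )
        for row in truth.itertuples()
    ]
    return merge_insertions(sites), truth


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[GeneModel], PeakCollection, list[InsertionSite], pd.DataFrame]:
    """Convenience: genome, peaks and insertions from one config."""
    genes = simulate_genome(config)
    peaks = simulate_peaks(genes, config)
    insertions, truth = simulate_insertions(genes, peaks, config)
    return genes, peaks, insertions, truth
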