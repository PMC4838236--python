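"""Association of insertions with chromatin-mark peak sets.

Two layers of analysis:

* **Global overlap** — for each insertion, which marks' peaks contain its
  point (exact half-open containment, no slop window), summarised as
  Venn-style counts over the power set of marks, with an optional pairwise
  hypergeometric p against a stated population.

* **Top-list overlap** — the top-N genes by insertion targeting are compared
  with the top-N genes of a peak-score ranking, and the probability of the
  observed overlap arising by chance is estimated by Monte-Carlo simulation:
  each draw samples the same number of genes uniformly without replacement
  from the full gene universe and records its overlap with the insertion
  top list. When the observed overlap is never reached, the empirical p is
  reported as the bound 1/n_sim with an explicit ``is_bound`` flag. p-values
  are conventionally reported as -log10(p) ("transformed p").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    DomainError,
    GenomicInterval,
    InsertionSite,
    PeakCollection,
    RankedGeneList,
    merge_intervals,
)


@dataclass
class OverlapCounts:
    """Per-combination insertion counts over the power set of marks."""

    marks: list[str]
    combination_counts: dict[frozenset, int]
    totals: dict[str, int]
    n_insertions: int

    def count(self, *marks: str) -> int:
        return self.combination_counts.get(frozenset(marks), 0)


@dataclass
class McOverlapResult:
    """Empirical significance of an observed top-list overlap."""

    observed_overlap: int
    n_sim: int
    exceed: int
    p: float
    is_bound: bool

    @property
    def transformed(self) -> float:
        return transform_p(self.p)


class _PointIndex:
    """Merged, sorted interval arrays per chromosome for point containment."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        starts: dict[str, list[int]] = {}
        ends: dict[str, list[int]] = {}
        ivs = list(intervals)
        for iv in merge_intervals(ivs) if ivs else []:
            starts.setdefault(iv.chrom, []).append(iv.start)
            ends.setdefault(iv.chrom, []).append(iv.end)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {
            c: (np.array(starts[c]), np.array(ends[c])) for c in starts
        }

    def contains(self, chrom: str, pos: int) -> bool:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        s, e = entry
        i = int(np.searchsorted(s, pos, side="right")) - 1
        return i >= 0 and pos < e[i]


def global_overlap(
    insertions: Sequence[InsertionSite],
    peak_collections: Sequence[PeakCollection],
) -> OverlapCounts:
    """Venn-style counts of insertions by the set of marks containing them.

    An insertion intersects a mark iff its point lies inside any peak of
    that mark; combination counts sum to the number of insertions.
    """
    if not peak_collections:
        raise DomainError("at least one peak collection is required")
    indexes = {pc.mark_name: _PointIndex(pc.intervals()) for pc in peak_collections}
    combos: dict[frozenset, int] = {}
    totals = {m: 0 for m in indexes}
    for ins in insertions:
        hit = frozenset(
            m for m, idx in indexes.items() if idx.contains(ins.chrom, ins.pos)
        )
        combos[hit] = combos.get(hit, 0) + 1
        for m in hit:
            totals[m] += 1
    return OverlapCounts(
        marks=[pc.mark_name for pc in peak_collections],
        combination_counts=combos,
        totals=totals,
        n_insertions=len(insertions),
    )


def pairwise_overlap_pvalue(
    insertions: Sequence[InsertionSite],
    peaks: PeakCollection,
    population_bp: int,
) -> float:
    """Hypergeometric p for insertion/peak overlap against a bp population.

    Population = ``population_bp`` positions (e.g. the union of gene
    windows); successes = bp covered by the mark's peak union; draws = the
    insertions; observed = insertions inside peaks. The population choice is
    the caller's and should be stated alongside the result.
    """
    from scipy import stats

    K = sum(iv.length for iv in merge_intervals(peaks.intervals()))
    if K > population_bp:
        raise DomainError("peak union exceeds the stated population")
    idx = _PointIndex(peaks.intervals())
    k = sum(1 for i in insertions if idx.contains(i.chrom, i.pos))
    return float(stats.hypergeom.sf(k - 1, population_bp, K, len(insertions)))


def top_gene_overlap(
    list_a: RankedGeneList,
    list_b: RankedGeneList,
    size: int = 500,
    expand_ties: bool = True,
) -> tuple[int, int, int]:
    """Overlap of the top ``size`` genes of two rankings.

    Score ties at the boundary expand the effective size when enabled.
    Returns (overlap, effective_size_a, effective_size_b).
    """
    top_a = list_a.top(size, expand_ties)
    top_b = list_b.top(size, expand_ties)
    overlap = len({s.upper() for s in top_a} & {s.upper() for s in top_b})
    return overlap, len(top_a), len(top_b)


def empirical_pvalue(exceed: int, n_sim: int, plus_one: bool = False) -> tuple[float, bool]:
    """Empirical Monte-Carlo p with the zero-exceedance bound convention.

    With ``exceed`` of ``n_sim`` simulations at or above the observed value,
    p = exceed/n_sim; when no simulation reaches it, the estimate is reported
    as the bound 1/n_sim (the true p is lower) with the flag set. The
    ``plus_one`` flag selects the (exceed+1)/(n_sim+1) estimator instead.
    """
    if n_sim < 1:
        raise DomainError(f"n_sim must be >= 1, got {n_sim}")
    if plus_one:
        return (exceed + 1) / (n_sim + 1), False
    if exceed == 0:
        return 1.0 / n_sim, True
    return exceed / n_sim, False


def mc_overlap_pvalue(
    universe: Sequence[str],
    top_list: Iterable[str],
    effective_size: int,
    observed: int,
    n_sim: int = 10**6,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    plus_one: bool = False,
) -> McOverlapResult:
    """Monte-Carlo p for an observed overlap with a fixed top list.

    Each simulation draws ``effective_size`` genes uniformly without
    replacement from ``universe`` and records the overlap with ``top_list``.
    Because the overlap of such a draw is exactly hypergeometric-distributed,
    the per-draw count is simulated directly from that distribution, which
    is distributionally identical to materialising the sampled gene subset.
    Deterministic given seed.
    """
    universe_set = {g.upper() for g in universe}
    if len(universe_set) != len(universe):
        raise DomainError("universe contains duplicate symbols")
    if effective_size > len(universe_set):
        raise DomainError("effective_size exceeds the universe")
    if effective_size < 1:
        raise DomainError("effective_size must be >= 1")
    if observed > effective_size:
        raise DomainError("observed overlap exceeds the sample size")
    if observed < 0 or n_sim < 1:
        raise DomainError("observed must be >= 0 and n_sim >= 1")
    t = len(universe_set & {g.upper() for g in top_list})
    if rng is None:
        rng = np.random.default_rng(seed)
    if observed == 0:
        exceed = n_sim  # every draw has overlap >= 0
    else:
        exceed = 0
        chunk = 10**7
        remaining = n_sim
        while remaining > 0:
            m = min(chunk, remaining)
            draws = rng.hypergeometric(t, len(universe_set) - t, effective_size, m)
            exceed += int((draws >= observed).sum())
            remaining -= m
    p, is_bound = empirical_pvalue(exceed, n_sim, plus_one=plus_one)
    return McOverlapResult(observed, n_sim, exceed, p, is_bound)


def transform_p(p: float) -> float:
    """-log10(p), the transformed-p reporting convention."""
    if not 0 < p <= 1:
        raise DomainError(f"p must lie in (0, 1], got {p}")
    return -math.log10(p)


def overlap_table(results: dict[str, McOverlapResult]) -> pd.DataFrame:
    """Summary table: mark, overlap count, p (or bound), transformed p."""
    rows = [
        {
            "mark": mark,
            "overlap_count": r.observed_overlap,
            "p": r.p,
            "transformed_p": r.transformed,
            "is_bound": r.is_bound,
        }
        for mark, r in results.items()
    ]
    return pd.DataFrame(
        rows, columns=["mark", "overlap_count", "p", "transformed_p", "is_bound"]
    )
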