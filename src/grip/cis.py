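"""Common insertion site (CIS) analysis by nearest-gene enrichment.

Each insertion is assigned to its nearest gene within a flanking window
(default 25 kb each side, capturing local regulatory elements). Per-gene
enrichment is then scored with an upper-tail hypergeometric test: insertions
are modelled as draws of base positions without replacement from the
"mappable genome", defined as the union of all gene windows. With k
insertions in a window of K bp, n insertions in the window union of N bp,

    p = P(X >= k),  X ~ Hypergeometric(N, K, n).

This one-sided tail coincides with the one-sided Fisher exact test on the
corresponding 2x2 table, so the result can be labelled as either. p-values
are corrected by Benjamini-Hochberg FDR, and top targets are selected by
significance first, then ranked by insertion count.

Note: assignment is exclusive (each insertion counts for one gene) while
each gene's test uses its full window length K even where windows overlap;
output headers document this construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import DomainError, GeneModel, InsertionSite, union_length


@dataclass
class CisResult:
    """Per-gene enrichment: counts, window geometry, raw p, FDR q, rank."""

    gene_id: str
    symbol: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    q: float = float("nan")
    rank: Optional[int] = None


def assign_insertions_to_genes(
    insertions: Sequence[InsertionSite],
    genes: Sequence[GeneModel],
    flank: int = 25000,
) -> tuple[dict[str, list[InsertionSite]], list[InsertionSite]]:
    """Assign each insertion to its nearest gene within the flanked window.

    An insertion is assigned to the gene whose window contains it and whose
    gene-body distance is minimal (0 inside the body); ties are broken by
    smaller distance to the TSS, then lexicographic gene_id. Insertions
    outside every window are returned unassigned.
    """
    if flank < 0:
        raise DomainError(f"flank must be >= 0, got {flank}")
    if not genes:
        raise DomainError("gene set must be non-empty")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        iv = g.window(flank).interval
        trees.setdefault(g.chrom, IntervalTree())[iv.start : iv.end] = g
    assigned: dict[str, list[InsertionSite]] = {}
    unassigned: list[InsertionSite] = []
    for ins in insertions:
        tree = trees.get(ins.chrom)
        hits = tree[ins.pos] if tree is not None else set()
        if not hits:
            unassigned.append(ins)
            continue
        best = min(
            (h.data for h in hits),
            key=lambda g: (g.body_distance(ins.pos), abs(ins.pos - g.tss), g.gene_id),
        )
        assigned.setdefault(best.gene_id, []).append(ins)
    return assigned, unassigned


def hypergeometric_cis_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p: P(X >= k), X ~ HG(N, K, n).

    Population N bp (window union), successes K bp (the gene's window),
    draws n (insertions in the union), observed k (insertions in the window).
    """
    if K > N:
        raise DomainError(f"window length K={K} exceeds population N={N}")
    if k > n:
        raise DomainError(f"k={k} exceeds draws n={n}")
    if K <= 0 or N <= 0 or n < 0 or k < 0:
        raise DomainError("counts must be non-negative with K, N positive")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    # extreme tails underflow to 0.0 in double precision; keep p in (0, 1]
    return max(p, float(np.finfo(float).tiny))


def bh_fdr(p_values: Sequence[float], n_tests: Optional[int] = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``n_tests`` lets the correction account for more tests than p-values are
    supplied for (the extra tests are treated as p = 1).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise DomainError("p-values must lie in (0, 1]")
    m = p.size if n_tests is None else int(n_tests)
    if m < p.size:
        raise DomainError(f"n_tests={m} < number of p-values {p.size}")
    padded = np.concatenate([p, np.ones(m - p.size)])
    return stats.false_discovery_control(padded, method="bh")[: p.size]


def cis_table(
    insertions: Sequence[InsertionSite],
    genes: Sequence[GeneModel],
    flank: int = 25000,
) -> pd.DataFrame:
    """Full nearest-gene CIS table for all genes with >= 1 assigned insertion.

    Columns: gene_id, symbol, k, K, n, N, p_raw, q. N is the union length of
    all gene windows; n counts only insertions inside that union.
    """
    assigned, _ = assign_insertions_to_genes(insertions, genes, flank)
    N = union_length([g.window(flank).interval for g in genes])
    n = sum(len(v) for v in assigned.values())
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for gene_id in sorted(assigned):
        g = by_id[gene_id]
        k = len(assigned[gene_id])
        K = g.window(flank).length
        rows.append(
            {
                "gene_id": gene_id,
                "symbol": g.symbol,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_raw": hypergeometric_cis_test(k, K, n, N),
            }
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "symbol", "k", "K", "n", "N", "p_raw"]
    )
    df["q"] = bh_fdr(df["p_raw"]) if len(df) else []
    return df


def rank_targets(
    results: pd.DataFrame,
    alpha: float = 0.05,
    top_n: int = 100,
    expand_ties: bool = False,
) -> pd.DataFrame:
    """Select and rank top CIS targets.

    Filters to p_raw < alpha, sorts by insertion count k descending (ties by
    smaller p_raw, then gene_id), and truncates to ``top_n``. When
    ``expand_ties`` is set and the k at the boundary is tied, the list is
    expanded to include all genes with that k.
    """
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    if top_n < 1:
        raise DomainError(f"top_n must be >= 1, got {top_n}")
    sig = results[results["p_raw"] < alpha].copy()
    sig = sig.sort_values(
        ["k", "p_raw", "gene_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    if len(sig) > top_n:
        if expand_ties:
            boundary_k = sig["k"].iloc[top_n - 1]
            cut = top_n
            while cut < len(sig) and sig["k"].iloc[cut] == boundary_k:
                cut += 1
            sig = sig.iloc[:cut]
        else:
            sig = sig.iloc[:top_n]
    sig = sig.copy()
    sig["rank"] = np.arange(1, len(sig) + 1)
    return sig
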