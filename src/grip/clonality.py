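"""Tests for post-integration clonal selection.

Integration itself is orientation-neutral, but enhancer-insertion activation
of a host gene is strongly orientation dependent, so outgrowth of selected
clones leaves two statistical fingerprints: proviral orientation bias at hot
loci (a "heads-tails" signature) and elevated junction-fragment copy numbers
at the selected sites. This module provides both tests: a per-gene Fisher
exact comparison of forward/reverse counts inside a gene cluster against the
remainder of the genome (with Bonferroni and Benjamini-Hochberg correction),
and a Welch t-test comparing copy numbers of top-target insertions against
the full dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cis import assign_insertions_to_genes, bh_fdr
from .core import DomainError, GeneModel, InsertionSite, Strand


@dataclass
class OrientationTable:
    """Forward/reverse insertion counts inside a gene cluster vs the rest."""

    gene_id: str
    fwd_in: int
    rev_in: int
    fwd_out: int
    rev_out: int
    p_fisher: float = float("nan")
    p_bonf: float = float("nan")
    p_bh: float = float("nan")


def orientation_bias_test(
    table: OrientationTable, alternative: str = "two-sided"
) -> float:
    """Fisher exact p for orientation bias in one gene cluster.

    Two-sided by point-probability summation over all tables with the fixed
    margins (the common convention); ``alternative`` may select a one-sided
    tail ('greater' tests forward excess in the cluster).
    """
    a, b, c, d = table.fwd_in, table.rev_in, table.fwd_out, table.rev_out
    if min(a, b, c, d) < 0:
        raise DomainError("negative count in orientation table")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise DomainError("orientation table has an all-zero margin")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def correct_orientation_pvalues(
    p_list: Sequence[float], n_tests: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni and Benjamini-Hochberg corrections over ``n_tests`` tests.

    ``n_tests`` defaults to the number of p-values but may exceed it when
    more genes were examined than are reported (e.g. findings corrected
    within a 100-gene screen).
    """
    p = np.asarray(p_list, dtype=float)
    m = p.size if n_tests is None else int(n_tests)
    if m < 1:
        raise DomainError(f"n_tests must be >= 1, got {m}")
    if m < p.size:
        raise DomainError(f"n_tests={m} < number of p-values {p.size}")
    bonf = np.minimum(1.0, p * m)
    bh = bh_fdr(p, n_tests=m) if p.size else p.copy()
    return bonf, bh


def orientation_bias_table(
    insertions: Sequence[InsertionSite],
    genes: Sequence[GeneModel],
    flank: int = 25000,
    gene_ids: Optional[Sequence[str]] = None,
    alternative: str = "two-sided",
    n_tests: Optional[int] = None,
) -> pd.DataFrame:
    """Per-gene heads-tails analysis over nearest-gene clusters.

    Clusters are the insertion groups from nearest-gene assignment with the
    same flanked window as the CIS analysis. Each cluster's forward/reverse
    split is compared to the remainder of the genome by Fisher exact test;
    ``gene_ids`` restricts testing to a subset (e.g. the top CIS targets)
    while corrections default to the number of genes examined.
    """
    assigned, _ = assign_insertions_to_genes(insertions, genes, flank)
    total_fwd = sum(1 for i in insertions if i.strand is Strand.FORWARD)
    total_rev = len(insertions) - total_fwd
    ids = sorted(assigned) if gene_ids is None else [g for g in gene_ids if g in assigned]
    rows = []
    for gene_id in ids:
        cluster = assigned[gene_id]
        fwd_in = sum(1 for i in cluster if i.strand is Strand.FORWARD)
        rev_in = len(cluster) - fwd_in
        tab = OrientationTable(
            gene_id, fwd_in, rev_in, total_fwd - fwd_in, total_rev - rev_in
        )
        tab.p_fisher = orientation_bias_test(tab, alternative=alternative)
        rows.append(tab)
    df = pd.DataFrame(
        [
            {
                "gene_id": t.gene_id,
                "fwd_in": t.fwd_in,
                "rev_in": t.rev_in,
                "fwd_out": t.fwd_out,
                "rev_out": t.rev_out,
                "p": t.p_fisher,
            }
            for t in rows
        ],
        columns=["gene_id", "fwd_in", "rev_in", "fwd_out", "rev_out", "p"],
    )
    if len(df):
        bonf, bh = correct_orientation_pvalues(df["p"], n_tests=n_tests or len(df))
        df["p_bonf"], df["p_bh"] = bonf, bh
    else:
        df["p_bonf"], df["p_bh"] = [], []
    return df


def copies_per_insertion(insertions: Sequence[InsertionSite]) -> float:
    """Mean junction-fragment copies per unique insertion (full precision)."""
    if not insertions:
        raise DomainError("empty insertion set")
    return float(np.mean([i.copies for i in insertions]))


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero, as reports print copy numbers."""
    factor = 10**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def copy_number_test(
    copies_top: Sequence[float], copies_all: Sequence[float]
) -> float:
    """Welch two-sample two-tailed p (unequal variance, Welch-Satterthwaite df).

    Compares copy numbers at the top target genes against the dataset as a
    whole; a non-significant result argues against clonal selection.
    """
    a = np.asarray(copies_top, dtype=float)
    b = np.asarray(copies_all, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("both samples must have size >= 2")
    if np.var(a) == 0 or np.var(b) == 0:
        raise DomainError(
            "a sample has zero variance; the Welch statistic is degenerate"
        )
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
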