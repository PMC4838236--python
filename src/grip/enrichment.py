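"""Enrichment of annotated gene sets among top integration targets.

The headline statistic is a chi-square goodness of fit of the count of
annotated genes in a top list against a genome-wide background proportion
(e.g. the fraction of all genes that are catalogued cancer drivers), with no
continuity correction. Fisher 2x2 comparisons cover two-list contrasts such
as upstream-regulator targeting, and a size-swept Monte-Carlo profile
measures how overlap between integration targets and an expression ranking
varies with the number of top genes considered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chromatin import McOverlapResult, mc_overlap_pvalue, top_gene_overlap
from .core import DomainError, GeneSet, RankedGeneList


@dataclass
class GofResult:
    """Chi-square goodness of fit of k/n annotated genes vs background p0."""

    k: int
    n: int
    p0: float
    chi2: float
    p: float


def gof_enrichment(k: int, n: int, p0: float) -> GofResult:
    """Chi-square (1 df, no continuity correction) enrichment test.

    chi2 = (k - n*p0)^2/(n*p0) + ((n-k) - n(1-p0))^2/(n(1-p0)); p is the
    upper tail of chi-square with one degree of freedom, a two-sided test of
    the observed annotation rate k/n against the background rate p0.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    if not 0 < p0 < 1:
        raise DomainError(f"p0 must lie in (0, 1), got {p0}")
    if not 0 <= k <= n:
        raise DomainError(f"k={k} outside [0, n={n}]")
    chi2, p = stats.chisquare([k, n - k], f_exp=[n * p0, n * (1 - p0)])
    return GofResult(k, n, p0, float(chi2), float(p))


def annotate_top_list(
    top_genes: Sequence[str], gene_set: GeneSet
) -> tuple[int, float, list[str]]:
    """Count top-list genes carrying the annotation (case-insensitive).

    Returns (k, fraction, matched symbols); the matched list lets callers
    report exactly which genes carried the annotation rather than silently
    aggregating.
    """
    if not top_genes:
        raise DomainError("empty top list")
    matched = sorted({g.upper() for g in top_genes} & gene_set.symbols)
    return len(matched), len(matched) / len(set(g.upper() for g in top_genes)), matched


def fisher_2x2(a: int, b: int, c: int, d: int, sided: str = "two-sided") -> float:
    """Fisher exact p for the 2x2 table [[a, b], [c, d]].

    ``sided`` is 'two-sided' (point-probability summation), 'greater' or
    'less' (conditional tails on the fixed margins).
    """
    if min(a, b, c, d) < 0:
        raise DomainError("counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise DomainError("table has an all-zero margin")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=sided)[1])


def gene_set_table(
    top_genes: Sequence[str], gene_sets: Iterable[GeneSet]
) -> pd.DataFrame:
    """Enrichment summary over several gene sets.

    Columns: set_name, k, n, fraction, p0, chi2, p. Sets without a stated
    background fraction get NaN statistics (no null to test against).
    """
    rows = []
    for gs in gene_sets:
        k, fraction, _ = annotate_top_list(top_genes, gs)
        n = len(set(g.upper() for g in top_genes))
        if gs.background_fraction is not None:
            res = gof_enrichment(k, n, gs.background_fraction)
            rows.append(
                {
                    "set_name": gs.name,
                    "k": k,
                    "n": n,
                    "fraction": fraction,
                    "p0": gs.background_fraction,
                    "chi2": res.chi2,
                    "p": res.p,
                }
            )
        else:
            rows.append(
                {
                    "set_name": gs.name,
                    "k": k,
                    "n": n,
                    "fraction": fraction,
                    "p0": float("nan"),
                    "chi2": float("nan"),
                    "p": float("nan"),
                }
            )
    return pd.DataFrame(
        rows, columns=["set_name", "k", "n", "fraction", "p0", "chi2", "p"]
    )


def expression_overlap_profile(
    grip_ranked: RankedGeneList,
    expr_ranked: RankedGeneList,
    sizes: Sequence[int],
    universe: Optional[Sequence[str]] = None,
    n_sim: int = 10**5,
    seed: Optional[int] = None,
    expand_ties: bool = True,
) -> pd.DataFrame:
    """Overlap of top integration targets with top expressed genes, by size.

    For each sample size s the top s of both rankings are intersected
    (boundary score ties expand the effective size) and the chance level is
    estimated by Monte-Carlo sampling of equally sized gene sets from
    ``universe`` (default: the union of both full rankings). Columns: size,
    observed, effective_size, p, transformed_p, is_bound.
    """
    if list(sizes) != sorted(sizes):
        raise DomainError("sizes must be ascending")
    if any(s > min(len(grip_ranked), len(expr_ranked)) for s in sizes):
        raise DomainError("a size exceeds a ranking length")
    if universe is None:
        universe = sorted(
            {g.upper() for g in grip_ranked.symbols}
            | {g.upper() for g in expr_ranked.symbols}
        )
    rng_seq = np.random.SeedSequence(seed)
    rows = []
    for s, child in zip(sizes, rng_seq.spawn(len(sizes))):
        observed, eff_a, eff_b = top_gene_overlap(
            grip_ranked, expr_ranked, size=s, expand_ties=expand_ties
        )
        result: McOverlapResult = mc_overlap_pvalue(
            universe,
            grip_ranked.top(s, expand_ties),
            effective_size=eff_b,
            observed=observed,
            n_sim=n_sim,
            rng=np.random.default_rng(child),
        )
        rows.append(
            {
                "size": s,
                "observed": observed,
                "effective_size": eff_b,
                "p": result.p,
                "transformed_p": result.transformed,
                "is_bound": result.is_bound,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["size", "observed", "effective_size", "p", "transformed_p", "is_bound"],
    )
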