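"""Independent brute-force oracles used to check the statistical routines.

Everything here is exact enumeration (rational arithmetic or explicit subset
generation) and deliberately shares no code with the implementation under
test.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ HG(N, K, n), by direct summation of pmf terms."""
    total = comb(N, n)
    lo = max(k, max(0, n - (N - K)))
    hi = min(K, n)
    acc = Fraction(0)
    for x in range(lo, hi + 1):
        acc += Fraction(comb(K, x) * comb(N - K, n - x), total)
    return acc


def fisher_pvalues(a: int, b: int, c: int, d: int) -> tuple[Fraction, Fraction, Fraction]:
    """(two_sided, greater, less) Fisher p for [[a,b],[c,d]] by enumeration.

    Works on the integer table weights comb(r1, x) * comb(r2, c1 - x), so
    point-probability comparisons (including knife-edge ties) are exact.
    Two-sided sums the probabilities of all tables with the fixed margins
    whose point probability does not exceed that of the observed table.
    """
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    total = comb(N, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    w_obs = comb(r1, a) * comb(r2, c1 - a)
    two = greater = less = 0
    for x in range(lo, hi + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        if w <= w_obs:
            two += w
        if x >= a:
            greater += w
        if x <= a:
            less += w
    return Fraction(two, total), Fraction(greater, total), Fraction(less, total)


def overlap_tail_exact(universe: list[str], top_list: set[str], size: int, observed: int) -> Fraction:
    """P(|sample ∩ top_list| >= observed) over all size-subsets of universe."""
    hits = 0
    total = 0
    for subset in combinations(universe, size):
        total += 1
        if len(set(subset) & top_list) >= observed:
            hits += 1
    return Fraction(hits, total)


def bh_step_up(p_values: list[float], m: int | None = None) -> list[float]:
    """Benjamini-Hochberg adjusted p-values from the step-up formula."""
    n = len(p_values)
    m = n if m is None else m
    order = sorted(range(n), key=lambda i: p_values[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p_values[i] * m / rank_from_top)
        adjusted[i] = min(1.0, running_min)
    return adjusted


def welch_permutation_p(a, b, n_perm: int, rng) -> float:
    """Two-sided permutation p for a difference in means (mean-shift null)."""
    import numpy as np

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[: a.size].mean() - perm[a.size :].mean()) >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)
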