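import math

import numpy as np
import pytest

from grip.chromatin import (
    empirical_pvalue,
    global_overlap,
    mc_overlap_pvalue,
    pairwise_overlap_pvalue,
    top_gene_overlap,
    transform_p,
)
from grip.core import (
    DomainError,
    GenomicInterval,
    InsertionSite,
    Peak,
    PeakCollection,
    RankedGeneList,
    Strand,
)

from oracles import overlap_tail_exact


def point(pos, chrom="chr1"):
    return InsertionSite(chrom, pos, Strand.FORWARD)


def collection(name, spans, chrom="chr1"):
    return PeakCollection(
        name, [Peak(GenomicInterval(chrom, s, e)) for s, e in spans]
    )


class TestGlobalOverlap:
    def test_no_peaks_puts_everything_in_none(self):
        marks = [PeakCollection("A", [])]
        counts = global_overlap([point(10), point(20)], marks)
        assert counts.count() == 2 and counts.totals["A"] == 0

    def test_double_membership_counted_once_per_combination(self):
        a = collection("A", [(0, 100)])
        b = collection("B", [(50, 150)])
        counts = global_overlap([point(75)], [a, b])
        assert counts.count("A", "B") == 1
        assert counts.count("A") == 0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        spans_a = [(int(s), int(s) + 30) for s in rng.integers(0, 1000, 4)]
        spans_b = [(int(s), int(s) + 50) for s in rng.integers(0, 1000, 3)]
        insertions = [point(int(p)) for p in rng.integers(0, 1050, 10)]
        counts = global_overlap(
            insertions, [collection("A", spans_a), collection("B", spans_b)]
        )

        def hit(p, spans):
            return any(s <= p < e for s, e in spans)

        expected: dict[frozenset, int] = {}
        for ins in insertions:
            combo = frozenset(
                m for m, spans in (("A", spans_a), ("B", spans_b))
                if hit(ins.pos, spans)
            )
            expected[combo] = expected.get(combo, 0) + 1
        assert counts.combination_counts == expected
        assert sum(counts.combination_counts.values()) == len(insertions)

    def test_half_open_peak_boundaries(self):
        a = collection("A", [(100, 200)])
        counts = global_overlap([point(100), point(199), point(200)], [a])
        assert counts.totals["A"] == 2

    def test_pairwise_hypergeometric_population(self):
        a = collection("A", [(0, 100)])
        p = pairwise_overlap_pvalue([point(10), point(500)], a, population_bp=1000)
        # k=1 of n=2 draws in K=100 of N=1000: P(X>=1) = 1 - C(900,2)/C(1000,2)
        expected = 1 - (900 * 899) / (1000 * 999)
        assert p == pytest.approx(expected, rel=1e-9)


class TestTopGeneOverlap:
    def ranked(self, symbols, scores=None):
        return RankedGeneList(
            list(symbols), scores or list(range(len(symbols), 0, -1))
        )

    def test_identical_lists(self):
        rl = self.ranked([f"G{i}" for i in range(20)])
        assert top_gene_overlap(rl, rl, size=10) == (10, 10, 10)

    def test_disjoint_lists(self):
        a = self.ranked([f"A{i}" for i in range(10)])
        b = self.ranked([f"B{i}" for i in range(10)])
        assert top_gene_overlap(a, b, size=5)[0] == 0

    def test_boundary_tie_expands_effective_size(self):
        scores = [9.0, 8.0, 7.0, 7.0, 7.0, 1.0]
        a = self.ranked([f"G{i}" for i in range(6)], list(scores))
        b = self.ranked([f"G{i}" for i in range(6)], list(scores))
        overlap, eff_a, eff_b = top_gene_overlap(a, b, size=3, expand_ties=True)
        assert (overlap, eff_a, eff_b) == (5, 5, 5)
        assert top_gene_overlap(a, b, size=3, expand_ties=False)[1] == 3

    def test_size_domain(self):
        rl = self.ranked(["A"])
        with pytest.raises(DomainError):
            top_gene_overlap(rl, rl, size=0)


class TestEmpiricalPvalue:
    def test_plain_ratio(self):
        assert empirical_pvalue(5, 100) == (0.05, False)

    def test_zero_exceedance_reports_bound(self):
        p, is_bound = empirical_pvalue(0, 10**6)
        assert p == 1e-6 and is_bound

    def test_plus_one_estimator(self):
        assert empirical_pvalue(0, 99, plus_one=True) == (0.01, False)


class TestMcOverlapPvalue:
    UNIVERSE = list("ABCDE")

    def test_observed_zero_gives_one(self):
        r = mc_overlap_pvalue(self.UNIVERSE, ["A"], 2, 0, n_sim=100, seed=0)
        assert r.p == 1.0 and r.exceed == 100

    def test_small_universe_matches_enumeration(self):
        # all C(5,2)=10 draws; only {A,B} overlaps both -> exact p = 1/10
        exact = float(overlap_tail_exact(self.UNIVERSE, {"A", "B"}, 2, 2))
        assert exact == pytest.approx(0.1)
        n_sim = 10**5
        r = mc_overlap_pvalue(self.UNIVERSE, ["A", "B"], 2, 2, n_sim=n_sim, seed=1)
        se = math.sqrt(exact * (1 - exact) / n_sim)
        assert abs(r.p - exact) < 3 * se

    def test_same_seed_is_bitwise_reproducible(self):
        a = mc_overlap_pvalue(self.UNIVERSE, ["A", "B"], 2, 1, n_sim=5000, seed=7)
        b = mc_overlap_pvalue(self.UNIVERSE, ["A", "B"], 2, 1, n_sim=5000, seed=7)
        assert (a.exceed, a.p, a.is_bound) == (b.exceed, b.p, b.is_bound)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(effective_size=9, observed=1),
            dict(effective_size=2, observed=3),
            dict(effective_size=0, observed=0),
        ],
    )
    def test_domain_errors(self, kwargs):
        with pytest.raises(DomainError):
            mc_overlap_pvalue(self.UNIVERSE, ["A"], n_sim=10, seed=0, **kwargs)


class TestTransformP:
    def test_known_values(self):
        assert transform_p(1.0) == 0.0
        assert transform_p(0.001402) == pytest.approx(2.853251986, abs=5e-10)

    def test_inverse_identity(self):
        for t in [0.0, 0.5, 3.0, 7.778151250383644]:
            assert transform_p(10 ** (-t)) == pytest.approx(t, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0, 1.5])
    def test_domain(self, bad):
        with pytest.raises(DomainError):
            transform_p(bad)
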