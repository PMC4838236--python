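import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from grip.cis import (
    assign_insertions_to_genes,
    bh_fdr,
    cis_table,
    hypergeometric_cis_test,
    rank_targets,
)
from grip.core import DomainError, GeneModel, Strand

from oracles import bh_step_up, hypergeom_upper_tail


class TestAssignment:
    def test_insertion_inside_body_assigned_at_distance_zero(self, two_genes, make_insertion):
        assigned, unassigned = assign_insertions_to_genes(
            [make_insertion(pos=105_000)], two_genes
        )
        assert list(assigned) == ["gA"] and not unassigned

    def test_insertion_beyond_flank_unassigned(self, two_genes, make_insertion):
        assigned, unassigned = assign_insertions_to_genes(
            [make_insertion(pos=140_001)], two_genes, flank=25_000
        )
        assert not assigned and len(unassigned) == 1

    def test_equidistant_tie_broken_by_tss_distance(self, make_insertion):
        # insertion ~5 kb from both gene bodies; TSS distances ~5 kb vs ~40 kb
        genes = [
            GeneModel("far_tss", "A", "chr1", Strand.FORWARD, 60_000, 95_000),
            GeneModel("near_tss", "B", "chr1", Strand.FORWARD, 105_001, 140_000),
        ]
        ins = make_insertion(pos=100_000)
        assert genes[0].body_distance(ins.pos) == genes[1].body_distance(ins.pos)
        assigned, _ = assign_insertions_to_genes([ins], genes)
        assert list(assigned) == ["near_tss"]

    def test_empty_insertion_set(self, two_genes):
        assigned, unassigned = assign_insertions_to_genes([], two_genes)
        assert assigned == {} and unassigned == []

    def test_conservation_of_insertions(self, hot_dataset):
        _, genes, _, insertions, _ = hot_dataset
        assigned, unassigned = assign_insertions_to_genes(insertions, genes)
        assert sum(map(len, assigned.values())) + len(unassigned) == len(insertions)


class TestHypergeometricTest:
    def test_zero_count_gives_one(self):
        assert hypergeometric_cis_test(0, 5, 10, 100) == 1.0

    def test_all_successes_gives_one(self):
        assert hypergeometric_cis_test(3, 50, 5, 50) == pytest.approx(1.0)

    def test_enumerated_pair_example(self):
        # N=10, K=5, n=2, k=2: 10 success pairs out of C(10,2)=45
        assert hypergeometric_cis_test(2, 5, 2, 10) == pytest.approx(10 / 45)

    @given(
        N=st.integers(2, 20),
        data=st.data(),
    )
    def test_matches_enumeration_oracle(self, N, data):
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        expected = float(hypergeom_upper_tail(k, K, n, N))
        assert hypergeometric_cis_test(k, K, n, N) == pytest.approx(expected, rel=1e-10)

    def test_non_increasing_in_k(self):
        ps = [hypergeometric_cis_test(k, 30, 20, 100) for k in range(0, 15)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("k,K,n,N", [(1, 200, 5, 100), (6, 50, 5, 100)])
    def test_domain_errors(self, k, K, n, N):
        with pytest.raises(DomainError):
            hypergeometric_cis_test(k, K, n, N)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    @given(
        p=st.lists(st.floats(1e-6, 1.0, exclude_min=False), min_size=1, max_size=20)
    )
    def test_adjusted_at_least_raw_and_matches_step_up(self, p):
        adjusted = bh_fdr(p)
        assert np.all(adjusted >= np.asarray(p) - 1e-12)
        np.testing.assert_allclose(adjusted, bh_step_up(p), rtol=1e-10)

    def test_extra_tests_treated_as_ones(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02], n_tests=4), bh_step_up([0.01, 0.02, 1.0, 1.0])[:2]
        )

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    def test_rejects_out_of_range(self):
        with pytest.raises(DomainError):
            bh_fdr([0.0, 0.5])


def _results(rows):
    return pd.DataFrame(rows, columns=["gene_id", "symbol", "k", "p_raw"])


class TestRankTargets:
    def test_nothing_significant_gives_empty_list(self):
        df = _results([("g1", "A", 7, 0.2), ("g2", "B", 3, 0.9)])
        assert len(rank_targets(df)) == 0

    def test_ordered_by_insertion_count(self):
        df = _results([("g1", "A", 3, 0.01), ("g2", "B", 7, 0.02)])
        out = rank_targets(df)
        assert list(out["gene_id"]) == ["g2", "g1"]
        assert list(out["rank"]) == [1, 2]

    def test_boundary_tie_expansion(self):
        rows = [(f"g{i}", f"S{i}", 10 - i, 0.001) for i in range(4)]
        rows += [("g9", "S9", 10 - 3, 0.001)]  # ties with the 4th-ranked k
        df = _results(rows)
        assert len(rank_targets(df, top_n=4, expand_ties=False)) == 4
        assert len(rank_targets(df, top_n=4, expand_ties=True)) == 5

    def test_alpha_domain(self):
        with pytest.raises(DomainError):
            rank_targets(_results([("g", "S", 1, 0.5)]), alpha=1.5)


class TestCisTable:
    def test_columns_and_invariants(self, hot_dataset, two_genes):
        _, genes, _, insertions, _ = hot_dataset
        df = cis_table(insertions, genes)
        assert list(df.columns) == ["gene_id", "symbol", "k", "K", "n", "N", "p_raw", "q"]
        assert (df["k"] <= df["n"]).all()
        assert (df["K"] <= df["N"]).all()
        assert ((df["p_raw"] > 0) & (df["p_raw"] <= 1)).all()
        assert (df["q"] >= df["p_raw"] - 1e-12).all()

    def test_hot_genes_dominate_top_ranks(self, hot_dataset):
        config, genes, _, insertions, _ = hot_dataset
        top10 = rank_targets(cis_table(insertions, genes), top_n=10)
        assert len(set(top10["gene_id"]) & set(config.hot_genes)) >= 8
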