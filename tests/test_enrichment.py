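"""Dual-test over-representation, the 1-Nk/T estimator, and the GO tree."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairde import (
    OverlapCounts,
    build_go_tree,
    chisq_p,
    count_overlap,
    enrichment_ratio,
    fisher_chisq_fdr,
    fisher_exact_p,
    run_enrichment,
)
from pairde.diffexpr import bh_adjust
from pairde.io import GeneSet, GeneSetCollection


def brute_force_hypergeom_tail(k, n_set, K, N):
    """Independent oracle: sum C(K,x)C(N-K,n-x)/C(N,n) over x >= k."""
    total = math.comb(N, n_set)
    return sum(math.comb(K, x) * math.comb(N - K, n_set - x)
               for x in range(k, min(K, n_set) + 1)) / total


class TestCountOverlap:
    def test_direct_counting(self):
        universe = [f"g{i}" for i in range(1000)]
        de = universe[:100]
        members = universe[95:105]  # 5 DE, 5 non-DE
        c = count_overlap(members, de, universe)
        assert (c.k, c.n_set, c.K, c.N_univ) == (5, 10, 100, 1000)

    def test_all_de_universe(self):
        universe = ["a", "b", "c"]
        c = count_overlap(["a", "b"], universe, universe)
        assert c.k == c.n_set == 2

    def test_disjoint_set(self):
        c = count_overlap(["x"], ["a"], ["a", "b", "x"])
        assert c.k == 0

    def test_members_outside_universe_ignored(self):
        c = count_overlap(["a", "zzz"], ["a"], ["a", "b"])
        assert (c.k, c.n_set) == (1, 1)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            count_overlap(["a"], [], [])

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            OverlapCounts(k=6, n_set=5, K=100, N_univ=1000)


class TestFisher:
    def test_k_zero_is_one(self):
        assert fisher_exact_p(OverlapCounts(0, 10, 100, 1000)) == 1.0

    def test_matches_enumeration(self):
        c = OverlapCounts(5, 10, 100, 1000)
        assert fisher_exact_p(c) == pytest.approx(
            brute_force_hypergeom_tail(5, 10, 100, 1000), rel=1e-12)

    def test_set_equals_universe(self):
        assert fisher_exact_p(OverlapCounts(7, 50, 7, 50)) == pytest.approx(1.0)

    def test_small_table_sweep(self):
        for N, K, n in [(20, 5, 8), (30, 10, 10), (15, 3, 12)]:
            for k in range(max(0, K + n - N), min(K, n) + 1):
                c = OverlapCounts(k, n, K, N)
                assert fisher_exact_p(c) == pytest.approx(
                    brute_force_hypergeom_tail(k, n, K, N), rel=1e-10)


class TestChisq:
    def test_observed_equals_expected_gives_p_one(self):
        # k = n_set*K/N exactly: 2 = 10*200/1000
        p, sub = chisq_p(OverlapCounts(2, 10, 200, 1000))
        assert p == pytest.approx(1.0)
        assert not sub

    def test_matches_direct_formula(self):
        c = OverlapCounts(5, 10, 100, 1000)
        obs = np.array([[5, 5], [95, 895]], dtype=float)
        row, col = obs.sum(1, keepdims=True), obs.sum(0, keepdims=True)
        exp = row @ col / obs.sum()
        stat = ((obs - exp) ** 2 / exp).sum()
        p, sub = chisq_p(c)
        assert not sub
        assert p == pytest.approx(stats.chi2.sf(stat, 1), rel=1e-12)

    def test_doubling_cells_doubles_statistic(self):
        p1, _ = chisq_p(OverlapCounts(5, 10, 100, 1000))
        p2, _ = chisq_p(OverlapCounts(10, 20, 200, 2000))
        stat1 = stats.chi2.isf(p1, 1)
        stat2 = stats.chi2.isf(p2, 1)
        assert stat2 == pytest.approx(2 * stat1, rel=1e-8)

    def test_sparse_expected_substitutes_fisher(self):
        c = OverlapCounts(2, 3, 5, 10000)
        p, sub = chisq_p(c)
        assert sub
        assert p == fisher_exact_p(c)


class TestDualTestFDR:
    def test_all_concordant_zero(self):
        rec = pd.DataFrame({"p_fisher": [0.001, 0.01, 0.1],
                            "p_chisq": [0.002, 0.02, 0.2]})
        assert np.array_equal(fisher_chisq_fdr(rec), np.zeros(3))

    def test_none_concordant_one(self):
        rec = pd.DataFrame({"p_fisher": [0.002, 0.02, 0.2],
                            "p_chisq": [0.001, 0.01, 0.1]})
        assert np.array_equal(fisher_chisq_fdr(rec), np.ones(3))

    def test_hand_evaluated_pattern(self):
        # Fisher order with concordance pattern (<, >=, <, >=):
        # raw (0, 1/2, 1/3, 1/2) -> monotone (0, 1/2, 1/2, 1/2)
        rec = pd.DataFrame({"p_fisher": [0.001, 0.01, 0.02, 0.04],
                            "p_chisq": [0.1, 0.001, 0.1, 0.001]})
        assert np.allclose(fisher_chisq_fdr(rec), [0.0, 0.5, 0.5, 0.5])

    def test_input_order_irrelevant(self):
        rec = pd.DataFrame({"p_fisher": [0.02, 0.001, 0.04, 0.01],
                            "p_chisq": [0.1, 0.1, 0.001, 0.001]})
        out = fisher_chisq_fdr(rec)
        assert np.allclose(out, [0.5, 0.0, 0.5, 0.5])

    def test_ties_share_larger_rank_value(self):
        rec = pd.DataFrame({"p_fisher": [0.01, 0.01],
                            "p_chisq": [0.1, 0.001]})
        # rank-2 raw = 1 - 1/2; both tied records share it
        assert np.allclose(fisher_chisq_fdr(rec), [0.5, 0.5])

    def test_always_in_unit_interval(self):
        rng = np.random.default_rng(9)
        rec = pd.DataFrame({"p_fisher": rng.uniform(size=100),
                            "p_chisq": rng.uniform(size=100)})
        out = fisher_chisq_fdr(rec)
        assert ((out >= 0) & (out <= 1)).all()
        order = np.argsort(rec["p_fisher"].to_numpy())
        assert (np.diff(out[order]) >= 0).all()

    def test_bh_switch(self):
        rec = pd.DataFrame({"p_fisher": [0.01, 0.02, 0.03],
                            "p_chisq": [0.5, 0.5, 0.5]})
        assert np.allclose(fisher_chisq_fdr(rec, method="bh"),
                           bh_adjust([0.01, 0.02, 0.03]))

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="p_chisq"):
            fisher_chisq_fdr(pd.DataFrame({"p_fisher": [0.1]}))


class TestEnrichmentRatio:
    def test_hand_arithmetic(self):
        assert enrichment_ratio(OverlapCounts(5, 10, 100, 1000)) == pytest.approx(5.0)

    def test_no_enrichment_is_one(self):
        assert enrichment_ratio(OverlapCounts(2, 10, 200, 1000)) == pytest.approx(1.0)

    def test_k_zero_is_zero(self):
        assert enrichment_ratio(OverlapCounts(0, 10, 100, 1000)) == 0.0

    def test_no_de_genes_undefined(self):
        assert math.isnan(enrichment_ratio(OverlapCounts(0, 10, 0, 1000)))

    def test_monotone_in_k_opposite_fisher(self):
        ps, ratios = [], []
        for k in range(0, 11):
            c = OverlapCounts(k, 10, 100, 1000)
            ps.append(fisher_exact_p(c))
            ratios.append(enrichment_ratio(c))
        assert (np.diff(ps) <= 1e-15).all()
        assert (np.diff(ratios) > 0).all()


class TestRunEnrichment:
    def test_planted_set_ranks_first(self, small_bundle):
        matrix, truth, collection, _, _ = small_bundle
        universe = set(truth.symbols.values())
        table = run_enrichment(collection, truth.de_symbols("up"),
                               truth.de_symbols("down"), universe)
        for direction in set(truth.enriched_sets.values()):
            sub = table[table["direction"] == direction]
            assert sub.iloc[0]["set_id"] in truth.enriched_sets

    def test_empty_up_list_gives_no_up_rows(self, small_bundle):
        _, truth, collection, _, _ = small_bundle
        universe = set(truth.symbols.values())
        table = run_enrichment(collection, set(), truth.de_symbols("down"), universe)
        assert (table["direction"] == "down").all()

    def test_fully_contained_set_ratio(self):
        universe = [f"g{i}" for i in range(200)]
        de_down = set(universe[:20])
        coll = GeneSetCollection({"S": GeneSet("S", "GO", tuple(universe[:10]))})
        table = run_enrichment(coll, set(), de_down, universe)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["direction"] == "down"
        assert row["ratio"] == pytest.approx(200 / 20)  # N_univ / K at k = n_set

    def test_pathway_mode_restricts_to_annotated_universe(self):
        universe = [f"g{i}" for i in range(100)]
        coll = GeneSetCollection({
            "A": GeneSet("A", "pathway", tuple(universe[:10])),
            "B": GeneSet("B", "pathway", tuple(universe[5:15])),
        })
        de = set(universe[:5]) | {"g99"}  # g99 carries no annotation
        table = run_enrichment(coll, de, set(), universe, mode="pathway")
        assert (table["N_univ"] == 15).all()
        assert (table["K"] == 5).all()


class TestGoTree:
    def test_shared_parent_becomes_connector(self):
        edges = pd.DataFrame({"child": ["A", "B", "P"], "parent": ["P", "P", "GP"]})
        tree = build_go_tree({"A": "up", "B": "down"}, edges)
        assert set(tree.nodes) == {"A", "B", "P"}
        assert tree.nodes["P"]["regulation"] == "connector"
        assert set(tree.edges) == {("P", "A"), ("P", "B")}

    def test_no_ontology_gives_isolated_terms(self):
        tree = build_go_tree({"A": "up", "B": "down"}, None)
        assert set(tree.nodes) == {"A", "B"}
        assert tree.number_of_edges() == 0

    def test_cycle_rejected(self):
        edges = pd.DataFrame({"child": ["A", "B"], "parent": ["B", "A"]})
        with pytest.raises(ValueError, match="cycle"):
            build_go_tree({"A": "up"}, edges)

    def test_random_dags_keep_significant_terms_reachable(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            n = 25
            rows = []
            for child in range(1, n):
                for parent in rng.choice(child, size=min(2, child), replace=False):
                    rows.append({"child": f"T{child}", "parent": f"T{parent}"})
            edges = pd.DataFrame(rows)
            sig = {f"T{i}": "up" for i in rng.choice(n, size=6, replace=False)}
            tree = build_go_tree(sig, edges)
            assert set(sig) <= set(tree.nodes)
            roots = [x for x in tree.nodes if tree.in_degree(x) == 0]
            reachable = set(roots)
            for r in roots:
                reachable |= nx.descendants(tree, r)
            assert set(sig) <= reachable
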