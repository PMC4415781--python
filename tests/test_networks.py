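"""Graph construction, degree/k-core topology, and key-gene ranking."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pairde import (
    SynthConfig,
    build_coexpression,
    build_gene_act,
    build_pathway_act,
    degree_centrality,
    kcore_decomposition,
    rank_key_genes,
)
from pairde.io import GeneSet, GeneSetCollection, InteractionTable
from pairde.synth import generate_paired_expression


def kcore_deletion_oracle(graph):
    """Brute-force core numbers by iterative deletion, per k."""
    cores = {n: 0 for n in graph.nodes}
    k = 1
    while True:
        g = graph.copy()
        while True:
            weak = [n for n in g.nodes if g.degree(n) < k]
            if not weak:
                break
            g.remove_nodes_from(weak)
        if g.number_of_nodes() == 0:
            return cores
        for n in g.nodes:
            cores[n] = k
        k += 1


def de_table(symbols, statuses):
    return pd.DataFrame({"probe_id": [f"p_{s}" for s in symbols],
                         "gene_symbol": symbols, "status": statuses})


class TestGeneAct:
    def test_planted_hub_in_hub_list(self, small_bundle, small_config):
        _, truth, _, interactions, _ = small_bundle
        genes = de_table(sorted(truth.de_symbols()), "up")
        g = build_gene_act(interactions, genes, hub_threshold=small_config.hub_degree - 2)
        assert set(truth.hub_genes) <= set(g.graph["hubs"])

    def test_no_de_genes_empty_graph(self, small_bundle):
        _, _, _, interactions, _ = small_bundle
        empty = de_table(["X"], ["ns"])
        g = build_gene_act(interactions, empty)
        assert g.number_of_nodes() == 0

    def test_induced_degrees_match_adjacency_oracle(self):
        rng = np.random.default_rng(11)
        genes = [f"G{i}" for i in range(30)]
        rows = []
        for _ in range(120):
            a, b = rng.choice(genes, size=2, replace=False)
            rows.append({"gene_a": a, "gene_b": b, "relation": "activation", "source": "x"})
        table = InteractionTable(rows=pd.DataFrame(rows))
        de = set(genes[:15])
        records = de_table(genes, ["up" if g in de else "ns" for g in genes])
        g = build_gene_act(table, records)
        adj = {x: set() for x in de}
        for r in table.rows.itertuples():
            if r.gene_a in de and r.gene_b in de:
                adj[r.gene_a].add(r.gene_b)
                adj[r.gene_b].add(r.gene_a)
        for node in g.nodes:
            assert g.degree(node) == len(adj[node])


class TestPathwayAct:
    def make_inputs(self):
        coll = GeneSetCollection({
            "PW1": GeneSet("PW1", "pathway", tuple(f"g{i}" for i in range(10))),
            "PW2": GeneSet("PW2", "pathway", tuple(f"g{i}" for i in range(5, 15))),
            "PW3": GeneSet("PW3", "pathway", ("z1", "z2", "z3")),
        })
        enr = pd.DataFrame({
            "set_id": ["PW1", "PW2", "PW3"],
            "direction": ["up", "up", "down"],
            "significant": [True, True, True],
        })
        return coll, enr

    def test_shared_de_genes_weight(self):
        coll, enr = self.make_inputs()
        de = {f"g{i}" for i in range(10)}  # shares g5..g9 -> 5 genes
        g = build_pathway_act(enr, coll, de, min_shared=3)
        assert g.has_edge("PW1", "PW2")
        assert g["PW1"]["PW2"]["weight"] == 5
        assert not g.has_edge("PW1", "PW3")

    def test_min_shared_above_any_overlap(self):
        coll, enr = self.make_inputs()
        g = build_pathway_act(enr, coll, {f"g{i}" for i in range(10)}, min_shared=6)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 3

    def test_no_self_edges(self):
        coll, enr = self.make_inputs()
        g = build_pathway_act(enr, coll, {f"g{i}" for i in range(15)})
        assert all(a != b for a, b in g.edges)


class TestCoexpression:
    def test_planted_tumor_module_denser_in_tumor(self):
        cfg = SynthConfig(n_probes=1200, n_de=80, n_modules=1, module_size=15,
                          module_groups=("tumor",), seed=17)
        matrix, truth = generate_paired_expression(cfg)
        probes = truth.modules["MOD00"]["probes"]
        sub = pd.DataFrame({"probe_id": probes,
                            "gene_symbol": [truth.symbols[p] for p in probes],
                            "status": "up"})
        gt = build_coexpression(matrix, "tumor", sub)
        gn = build_coexpression(matrix, "normal", sub)
        n_pairs = len(probes) * (len(probes) - 1) / 2
        assert gt.number_of_edges() / n_pairs > 0.5
        assert gn.number_of_edges() < 0.1 * n_pairs

    def test_too_few_samples_rejected(self, small_bundle):
        matrix, truth, _, _, _ = small_bundle
        tiny = matrix.subset_samples(list(matrix.sample_ids[:4]))  # 2 tumor, 2 normal
        sub = pd.DataFrame({"probe_id": list(matrix.probe_ids[:5]),
                            "gene_symbol": [f"G{i}" for i in range(5)],
                            "status": "up"})
        with pytest.raises(ValueError, match="tumor"):
            build_coexpression(tiny, "tumor", sub)

    def test_constant_gene_skipped(self, small_bundle):
        matrix, _, _, _, _ = small_bundle
        m = matrix.subset_samples(list(matrix.sample_ids))
        m.values.iloc[0, :] = 7.0  # constant probe
        sub = pd.DataFrame({"probe_id": list(m.probe_ids[:6]),
                            "gene_symbol": [f"G{i}" for i in range(6)],
                            "status": "up"})
        g = build_coexpression(m, "tumor", sub)
        assert "G0" not in g.nodes


class TestTopology:
    def test_triangle_degrees_and_cores(self):
        g = nx.cycle_graph(3)
        assert set(degree_centrality(g).values()) == {2}
        assert set(kcore_decomposition(g).values()) == {2}

    def test_path_cores_are_one(self):
        g = nx.path_graph(4)
        assert set(kcore_decomposition(g).values()) == {1}

    def test_star_degrees(self):
        g = nx.star_graph(5)
        d = degree_centrality(g)
        assert d[0] == 5
        assert all(d[i] == 1 for i in range(1, 6))

    def test_random_graph_degree_matrix_oracle(self):
        g = nx.gnp_random_graph(40, 0.15, seed=3)
        a = nx.to_numpy_array(g)
        d = degree_centrality(g)
        for i, node in enumerate(g.nodes):
            assert d[node] == int(a[i].sum())

    def test_kcore_matches_deletion_oracle_on_random_graphs(self):
        rng = np.random.default_rng(12)
        for i in range(30):
            n = int(rng.integers(5, 50))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.05, 0.4)), seed=int(rng.integers(1 << 30)))
            cores = kcore_decomposition(g)
            assert cores == kcore_deletion_oracle(g)
            degrees = degree_centrality(g)
            assert all(cores[x] <= degrees[x] for x in g.nodes)

    def test_self_loop_rejected(self):
        g = nx.Graph([("A", "A"), ("A", "B")])
        with pytest.raises(ValueError, match="self-loop"):
            kcore_decomposition(g)

    def test_planted_near_clique_has_high_core(self):
        cfg = SynthConfig(n_probes=1000, n_de=60, n_modules=1, module_size=15,
                          module_r=0.97, module_groups=("tumor",), seed=19)
        matrix, truth = generate_paired_expression(cfg)
        probes = truth.modules["MOD00"]["probes"]
        sub = pd.DataFrame({"probe_id": probes,
                            "gene_symbol": [truth.symbols[p] for p in probes],
                            "status": "up"})
        g = build_coexpression(matrix, "tumor", sub)
        cores = kcore_decomposition(g)
        assert max(cores.values()) >= len(probes) - 1 - 2


class TestRankKeyGenes:
    def test_degree_primary_sort(self):
        g = nx.Graph()
        g.add_edges_from(("HEG1", f"x{i}") for i in range(15))
        g.add_edges_from(("COL14A1", f"y{i}") for i in range(14))
        out = rank_key_genes(g, top_n=2)
        assert list(out["gene"]) == ["HEG1", "COL14A1"]

    def test_alphabetical_tiebreak(self):
        g = nx.Graph([("B", "C"), ("C", "A"), ("A", "B")])
        out = rank_key_genes(g)
        assert list(out["gene"]) == ["A", "B", "C"]

    def test_top_n_larger_than_graph(self):
        g = nx.path_graph(3)
        assert len(rank_key_genes(g, top_n=50)) == 3
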