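"""Graph products: Gene-Act, Pathway-Act, and group-wise co-expression networks.

All three products are undirected simple graphs for topology purposes
(degree centrality and k-core decomposition), with relation types kept as
edge attributes.  Key genes are ranked by (degree desc, core desc, gene
asc) — the genes that hold the network together.
"""

from __future__ import annotations

import itertools
import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSetCollection, InteractionTable

logger = logging.getLogger(__name__)


def build_gene_act(
    interactions: InteractionTable,
    de_records: pd.DataFrame,
    hub_threshold: int = 25,
) -> nx.Graph:
    """Interaction subgraph induced on differentially expressed genes.

    Nodes carry ``regulation`` (up/down) from the DE table; ``graph.graph
    ['hubs']`` lists nodes with degree > *hub_threshold*.
    """
    de = de_records[de_records["status"] != "ns"]
    status = dict(zip(de["gene_symbol"], de["status"]))
    g = nx.Graph()
    for a, b, rel in interactions.rows[["gene_a", "gene_b", "relation"]].itertuples(index=False):
        if a in status and b in status:
            g.add_edge(a, b, type=rel)
        else:
            # DE genes whose partners are all non-DE stay as isolated nodes
            for node in (a, b):
                if node in status:
                    g.add_node(node)
    if g.number_of_edges() == 0:
        logger.warning("gene-act network is empty: no interaction joins two DE genes")
    for node in g.nodes:
        g.nodes[node]["kind"] = "gene"
        g.nodes[node]["regulation"] = status[node]
    g.graph["hubs"] = sorted(n for n, d in g.degree() if d > hub_threshold)
    g.graph["hub_threshold"] = hub_threshold
    return g


def build_pathway_act(
    enrichment_table: pd.DataFrame,
    collection: GeneSetCollection,
    de_genes,
    min_shared: int = 3,
) -> nx.Graph:
    """Pathway interaction graph: significant pathways joined by shared DE genes.

    Nodes are significant rows of the pathway enrichment table (colored by
    direction); an edge joins two pathways iff they share at least
    *min_shared* differential genes, weighted by the shared count.
    """
    de_genes = set(de_genes)
    sig = enrichment_table[enrichment_table["significant"]]
    g = nx.Graph()
    members: dict[str, set] = {}
    for sid, direction in zip(sig["set_id"], sig["direction"]):
        if sid in g:  # a set significant in both directions keeps its first color
            continue
        g.add_node(sid, kind="pathway", regulation=direction)
        members[sid] = set(collection.sets[sid].members) & de_genes
    for a, b in itertools.combinations(sorted(members), 2):
        shared = len(members[a] & members[b])
        if shared >= min_shared:
            g.add_edge(a, b, type="interaction", weight=shared)
    return g


def build_coexpression(
    matrix: ExpressionMatrix,
    group: str,
    gene_subset: pd.DataFrame | None = None,
    r_threshold: float = 0.8,
    p_threshold: float = 0.01,
) -> nx.Graph:
    """Pearson co-expression graph within one tissue group.

    *gene_subset* is a DE table (gene-level: columns ``gene_symbol``,
    ``probe_id``, ``status``); by default edges are computed between all its
    genes.  An edge joins two genes iff |r| >= *r_threshold* and the
    correlation-test P (t transform, n-2 df) < *p_threshold*; the weight is
    r.  Genes with zero variance in the group are skipped with a logged
    count.
    """
    samples = matrix.samples_in(group)
    n = len(samples)
    if n < 4:
        raise ValueError(f"co-expression needs >= 4 {group} samples, found {n}")
    if gene_subset is None:
        probe_ids = list(matrix.probe_ids)
        genes = probe_ids
        regulation = {}
    else:
        probe_ids = list(gene_subset["probe_id"])
        genes = list(gene_subset["gene_symbol"])
        regulation = dict(zip(gene_subset["gene_symbol"], gene_subset.get("status", "")))
    x = matrix.values.loc[probe_ids, samples].to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("skipping %d constant genes in %s co-expression", int(constant.sum()), group)
    g = nx.Graph()
    for gene in np.array(genes)[~constant]:
        g.add_node(gene, kind="gene", regulation=regulation.get(gene, ""))
    keep = np.flatnonzero(~constant)
    if keep.size >= 2:
        r = np.corrcoef(x[keep])
        np.clip(r, -1.0, 1.0, out=r)
        df = n - 2
        with np.errstate(divide="ignore"):
            tstat = r * np.sqrt(df / np.maximum(1.0 - r ** 2, 1e-300))
        pmat = 2.0 * stats.t.sf(np.abs(tstat), df=df)
        for i, j in zip(*np.triu_indices(keep.size, k=1)):
            gi, gj = genes[keep[i]], genes[keep[j]]
            if gi == gj:
                continue
            if abs(r[i, j]) >= r_threshold and pmat[i, j] < p_threshold:
                g.add_edge(gi, gj, type="coexpression", weight=float(r[i, j]))
    g.graph["group"] = group
    g.graph["r_threshold"] = r_threshold
    g.graph["p_threshold"] = p_threshold
    return g


def degree_centrality(graph: nx.Graph) -> dict[str, int]:
    """Simple (unweighted, undirected) degree per node."""
    return {n: int(d) for n, d in graph.degree()}


def kcore_decomposition(graph: nx.Graph) -> dict[str, int]:
    """Core number per node: the largest k such that the node survives
    iterative deletion of all nodes with degree < k.  Self-loops rejected."""
    if any(a == b for a, b in graph.edges):
        raise ValueError("k-core decomposition requires a simple graph without self-loops")
    cores = nx.core_number(graph)
    for node, core in cores.items():
        graph.nodes[node]["core"] = int(core)
    return {n: int(c) for n, c in cores.items()}


def rank_key_genes(graph: nx.Graph, top_n: int = 20) -> pd.DataFrame:
    """Key-gene table sorted by (degree desc, core desc, gene asc), top *top_n*."""
    degrees = degree_centrality(graph)
    cores = kcore_decomposition(graph)
    rows = [{"gene": n, "degree": degrees[n], "core": cores[n]} for n in graph.nodes]
    out = pd.DataFrame(rows, columns=["gene", "degree", "core"])
    out = out.sort_values(["degree", "core", "gene"],
                          ascending=[False, False, True], kind="stable")
    return out.head(top_n).reset_index(drop=True)
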