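"""Gene-set over-representation with dual Fisher / chi-square testing.

Each gene set is scored against a differential gene list via the 2x2 table
(k differential genes in the set, n_set universe genes in the set, K
differential genes in the universe, N universe genes).  Two tests run per
set — the one-sided hypergeometric (Fisher) upper tail and the Pearson
chi-square on the implied table — and the multiple-testing correction is
the dual-test estimator

    FDR_i = 1 - Nk_i / T_i

where, walking the sets in ascending Fisher-P order, ``T_i`` is the rank
and ``Nk_i`` counts sets among the top i whose Fisher P falls below their
chi-square P.  A running maximum makes the estimate non-decreasing in
Fisher P; plain Benjamini-Hochberg on the Fisher P is available as an
alternative.  The enrichment ratio is observed over expected:
``(k / n_set) / (K / N)``.

GO mode counts against the whole symbol universe of the array; pathway mode
restricts both universe and differential list to genes carrying at least
one pathway annotation, matching the pathway enrichment score
``(ng / na) / (Ng / Na)``.
"""

from __future__ import annotations

import dataclasses
import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class OverlapCounts:
    """2x2 overlap counts: set-vs-differential membership in the universe."""

    k: int        # differential genes in the set
    n_set: int    # universe genes in the set
    K: int        # differential genes in the universe
    N_univ: int   # universe size

    def __post_init__(self) -> None:
        if self.N_univ <= 0:
            raise ValueError("universe must be non-empty")
        if not (0 <= self.k <= min(self.n_set, self.K)):
            raise ValueError("k must satisfy 0 <= k <= min(n_set, K)")
        if self.n_set > self.N_univ or self.K > self.N_univ:
            raise ValueError("set and differential counts cannot exceed the universe")

    def table(self) -> np.ndarray:
        """The implied 2x2 contingency table (DE x in-set)."""
        return np.array([
            [self.k, self.n_set - self.k],
            [self.K - self.k, self.N_univ - self.K - (self.n_set - self.k)],
        ], dtype=float)


def count_overlap(members, de_genes, universe) -> OverlapCounts:
    """Exact overlap counts; members outside the universe are ignored."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    de = set(de_genes)
    if not de <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    members = set(members)
    outside = len(members - universe)
    if outside:
        logger.debug("ignoring %d set members outside the universe", outside)
    inset = members & universe
    return OverlapCounts(k=len(inset & de), n_set=len(inset), K=len(de), N_univ=len(universe))


def fisher_exact_p(counts: OverlapCounts) -> float:
    """One-sided over-representation P: P(X >= k), X ~ Hypergeom(N, K, n_set)."""
    return float(stats.hypergeom.sf(counts.k - 1, counts.N_univ, counts.K, counts.n_set))


def chisq_p(counts: OverlapCounts) -> tuple[float, bool]:
    """Pearson chi-square P (1 df, no continuity correction) on the 2x2 table.

    When any expected cell is below 1 the asymptotic test is unreliable; the
    Fisher P is substituted and the second return value flags it.
    """
    obs = counts.table()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    if (expected < 1.0).any():
        return fisher_exact_p(counts), True
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = float(np.nansum((obs - expected) ** 2 / expected))
    return float(stats.chi2.sf(stat, df=1)), False


def enrichment_ratio(counts: OverlapCounts) -> float:
    """Observed over expected differential fraction: (k/n_set) / (K/N)."""
    if counts.K == 0:
        return float("nan")  # undefined without any differential gene
    if counts.n_set == 0:
        raise ValueError("enrichment ratio requires a non-empty set")
    return (counts.k / counts.n_set) / (counts.K / counts.N_univ)


def fisher_chisq_fdr(records: pd.DataFrame, method: str = "paper") -> np.ndarray:
    """Dual-test FDR per record, in input order.

    ``method='paper'``: sort by Fisher P ascending; at rank i (1-based)
    the raw estimate is ``1 - Nk/i`` with Nk the count of top-i records
    whose Fisher P < chi-square P; ties in Fisher P share the value at the
    group's largest rank; a running maximum down the ranking enforces
    monotonicity in Fisher P.  ``method='bh'`` substitutes plain
    Benjamini-Hochberg on the Fisher P.
    """
    for col in ("p_fisher", "p_chisq"):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
        if records[col].isna().any():
            raise ValueError(f"missing values in {col!r}")
    if method == "bh":
        return bh_adjust(records["p_fisher"].to_numpy())
    if method != "paper":
        raise ValueError(f"unknown FDR method {method!r}")
    pf = records["p_fisher"].to_numpy(dtype=float)
    pc = records["p_chisq"].to_numpy(dtype=float)
    order = np.argsort(pf, kind="stable")
    concordant = (pf < pc)[order]
    ranks = np.arange(1, pf.size + 1, dtype=float)
    raw = 1.0 - np.cumsum(concordant) / ranks
    # ties in Fisher P share the larger rank's value
    pf_sorted = pf[order]
    for start in np.flatnonzero(np.r_[True, pf_sorted[1:] != pf_sorted[:-1]]):
        stop = start + 1
        while stop < pf.size and pf_sorted[stop] == pf_sorted[start]:
            stop += 1
        raw[start:stop] = raw[stop - 1]
    monotone = np.maximum.accumulate(raw)
    out = np.empty_like(monotone)
    out[order] = monotone
    return out


def run_enrichment(
    collection: GeneSetCollection,
    de_up,
    de_down,
    universe,
    mode: str = "GO",
    fdr_method: str = "paper",
    p_threshold: float = 0.01,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Score every (set, direction) pair; one table sorted by Fisher P.

    In pathway mode the universe and both differential lists are first
    restricted to genes with at least one annotation in the collection.
    Significance = Fisher P < p_threshold and FDR < fdr_threshold.
    """
    if mode not in ("GO", "pathway"):
        raise ValueError("mode must be 'GO' or 'pathway'")
    universe = set(universe)
    de_up, de_down = set(de_up), set(de_down)
    if mode == "pathway":
        annotated = collection.all_members() & universe
        universe = annotated
        de_up &= annotated
        de_down &= annotated
    rows = []
    for direction, de in (("up", de_up), ("down", de_down)):
        if not de:
            logger.warning("empty %s-regulated gene list; %s table will be empty", direction, direction)
            continue
        for sid in sorted(collection.sets):
            s = collection.sets[sid]
            counts = count_overlap(s.members, de, universe)
            if counts.n_set == 0:
                continue
            p_f = fisher_exact_p(counts)
            p_c, substituted = chisq_p(counts)
            rows.append({
                "set_id": sid, "name": s.name, "category": s.category,
                "direction": direction,
                "k": counts.k, "n_set": counts.n_set, "K": counts.K, "N_univ": counts.N_univ,
                "p_fisher": p_f, "p_chisq": p_c, "chisq_substituted": substituted,
                "ratio": enrichment_ratio(counts),
            })
    if not rows:
        return pd.DataFrame(columns=["set_id", "name", "category", "direction", "k", "n_set",
                                     "K", "N_univ", "p_fisher", "p_chisq", "chisq_substituted",
                                     "ratio", "fdr", "significant"])
    table = pd.DataFrame(rows)
    parts = []
    for direction, sub in table.groupby("direction", sort=True):
        sub = sub.copy()
        sub["fdr"] = fisher_chisq_fdr(sub, method=fdr_method)
        parts.append(sub)
    table = pd.concat(parts, ignore_index=True)
    table["significant"] = (table["p_fisher"] < p_threshold) & (table["fdr"] < fdr_threshold)
    return table.sort_values(["p_fisher", "set_id", "direction"], kind="stable").reset_index(drop=True)


def build_go_tree(
    significant: dict[str, str],
    ontology_edges: pd.DataFrame | None,
) -> nx.DiGraph:
    """Induce the ontology tree over significant terms.

    *significant* maps term id -> direction (``up``/``down``).
    *ontology_edges* is a child->parent table (columns ``child``, ``parent``)
    and must be acyclic.  The output contains the significant terms plus the
    minimal connecting ancestors — non-significant ancestors that branch
    toward at least two significant lineages — marked ``connector``.
    Edges run parent -> child.
    """
    tree = nx.DiGraph()
    for term, direction in significant.items():
        tree.add_node(term, kind="term", regulation=direction)
    if ontology_edges is None or len(ontology_edges) == 0:
        return tree
    dag = nx.DiGraph()
    for child, parent in ontology_edges[["child", "parent"]].itertuples(index=False):
        dag.add_edge(child, parent)  # edge direction: child -> parent
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValueError(f"ontology edges contain a cycle: {cycle}")

    sig = set(significant)
    # for each node, the set of significant terms in its descendant closure
    reached: dict[str, set[str]] = {}
    for node in nx.topological_sort(dag):
        acc = {node} & sig
        for pred in dag.predecessors(node):  # children in ontology terms
            acc |= reached.get(pred, set())
        reached[node] = acc

    def children_in(node) -> list:
        return list(dag.predecessors(node))

    connectors = set()
    for node in dag.nodes:
        if node in sig:
            continue
        branches = sum(1 for c in children_in(node) if reached.get(c))
        if branches >= 2:
            connectors.add(node)
    keep = sig | connectors
    for node in connectors:
        tree.add_node(node, kind="term", regulation="connector")
    for child, parent in dag.edges:
        if child in keep and parent in keep:
            tree.add_edge(parent, child, type="ontology")
    # attach significant terms to their nearest kept ancestor when the
    # direct parent was pruned
    for term in sig:
        if term not in dag or tree.in_degree(term) > 0:
            continue
        frontier = list(dag.successors(term))
        seen = set(frontier)
        while frontier:
            anc = frontier.pop(0)
            if anc in keep and anc != term:
                tree.add_edge(anc, term, type="ontology")
                break
            for nxt in dag.successors(anc):
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
    return tree
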