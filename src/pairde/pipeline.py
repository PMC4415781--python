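"""End-to-end orchestration: generate/ingest -> normalize -> QC -> DE ->
enrichment -> networks -> qPCR concordance, with a machine-readable manifest.

Stages run in a fixed order; each enabled stage persists its outputs under
the configured work directory before the next stage starts, so a failure in
stage *k* leaves stages < *k* intact.  The manifest records the config
snapshot, software version, per-stage output checksums and record counts;
deterministic stages reproduce identical checksums on rerun.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import STAGES, PipelineConfig
from .diffexpr import de_summary, run_de
from .enrichment import build_go_tree, run_enrichment
from .io import (
    collapse_by_symbol,
    read_expression_tsv,
    read_gmt,
    read_interactions,
    read_json,
    read_qpcr_tsv,
    write_graph_sif,
    write_json,
    write_table,
)
from .networks import (
    build_coexpression,
    build_gene_act,
    build_pathway_act,
    rank_key_genes,
)
from .preprocess import qc_flag_samples, quantile_normalize
from .qpcr import concordance, fold_changes, per_gene_fold_change
from .synth import generate_bundle

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; earlier stages' outputs are intact."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclasses.dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict[str, dict] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"config": self.config, "version": self.version, "stages": self.stages}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _record(manifest: RunManifest, workdir: Path, stage: str,
            outputs: list[Path], counts: dict) -> None:
    manifest.stages[stage] = {
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        "counts": counts,
    }
    write_json(manifest.to_dict(), workdir / "manifest.json")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every enabled stage in order and return the manifest."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=__version__)
    state: dict = {}

    runners = {
        "simulate": _stage_simulate,
        "normalize": _stage_normalize,
        "qc": _stage_qc,
        "de": _stage_de,
        "enrichment": _stage_enrichment,
        "networks": _stage_networks,
        "qpcr": _stage_qpcr,
    }
    for stage in STAGES:
        if not config.stages.get(stage, True):
            continue
        try:
            outputs, counts = runners[stage](config, workdir, state)
        except StageError:
            write_json(manifest.to_dict(), workdir / "manifest.json")
            raise
        except Exception as exc:
            write_json(manifest.to_dict(), workdir / "manifest.json")
            raise StageError(stage, str(exc)) from exc
        _record(manifest, workdir, stage, outputs, counts)
        logger.info("stage %s: %s", stage, counts)
    write_json(manifest.to_dict(), workdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _load_inputs(config: PipelineConfig, state: dict) -> None:
    if "matrix" in state:
        return
    if config.expression_tsv is None or config.design_tsv is None:
        raise StageError("normalize", "missing expression/design input "
                         "(enable the simulate stage or provide expression_tsv/design_tsv)")
    state["matrix"] = read_expression_tsv(config.expression_tsv, config.design_tsv)
    if config.gmt:
        state["collection"] = read_gmt(config.gmt)
    if config.interactions_tsv:
        state["interactions"] = read_interactions(config.interactions_tsv)
    if config.qpcr_tsv:
        state["qpcr_table"] = read_qpcr_tsv(config.qpcr_tsv)


def _stage_simulate(config: PipelineConfig, workdir: Path, state: dict):
    synth_cfg = config.synth_config()
    matrix, truth, collection, interactions, qpcr_table = generate_bundle(synth_cfg, workdir)
    state.update(matrix=matrix, truth=truth, collection=collection,
                 interactions=interactions, qpcr_table=qpcr_table)
    outputs = [workdir / n for n in
               ("expression.tsv", "design.tsv", "gene_sets.gmt",
                "interactions.tsv", "ground_truth.json")]
    if qpcr_table is not None:
        outputs.append(workdir / "qpcr.tsv")
    counts = {"probes": matrix.n_probes, "pairs": len(matrix.complete_pairs()),
              "gene_sets": len(collection), "interactions": len(interactions)}
    return outputs, counts


def _stage_normalize(config: PipelineConfig, workdir: Path, state: dict):
    _load_inputs(config, state)
    from .io import write_expression_tsv
    state["matrix"] = quantile_normalize(state["matrix"])
    write_expression_tsv(state["matrix"], workdir / "normalized.tsv",
                         workdir / "normalized_design.tsv")
    return ([workdir / "normalized.tsv", workdir / "normalized_design.tsv"],
            {"probes": state["matrix"].n_probes,
             "samples": len(state["matrix"].sample_ids)})


def _stage_qc(config: PipelineConfig, workdir: Path, state: dict):
    _load_inputs(config, state)
    report = qc_flag_samples(state["matrix"], alpha=config.qc_alpha)
    samples = report.samples.reset_index(names="sample")
    pairs = report.pairs.reset_index()
    write_table(samples, workdir / "qc_samples.tsv")
    write_table(pairs, workdir / "qc_pairs.tsv")
    state["matrix"] = report.apply(state["matrix"])
    state["qc_report"] = report
    return ([workdir / "qc_samples.tsv", workdir / "qc_pairs.tsv"],
            {"flagged_samples": int(samples["outlier"].sum()) if "outlier" in samples else 0,
             "kept_pairs": len(report.kept_pairs), "skipped": report.skipped})


def _stage_de(config: PipelineConfig, workdir: Path, state: dict):
    _load_inputs(config, state)
    de = run_de(state["matrix"], config.fc_threshold, config.p_threshold,
                config.fdr_threshold)
    state["de"] = de
    genes = collapse_by_symbol(de)
    state["de_genes"] = genes
    write_table(de, workdir / "de_table.tsv")
    write_table(genes, workdir / "de_genes.tsv")
    summary = de_summary(de)
    write_table(summary, workdir / "de_summary.tsv")
    # Table-1 schema excerpt: top differential probes by |log2FC| within calls
    called = de[de["status"] != "ns"]
    top = called.reindex(called["log2fc"].abs().sort_values(ascending=False).index)
    table1 = top.head(2 * config.top_n)[["probe_id", "gene_symbol", "log2fc", "p", "fdr"]]
    table1 = table1.rename(columns={"probe_id": "Gene ID", "gene_symbol": "Symbol",
                                    "log2fc": "Log2FC", "p": "P-value", "fdr": "FDR"})
    write_table(table1, workdir / "top_differential.tsv")
    counts = {"up": int((de["status"] == "up").sum()),
              "down": int((de["status"] == "down").sum()),
              "by_biotype": {f"{r.biotype}_{d}": int(getattr(r, d))
                             for r in summary.itertuples() for d in ("up", "down")}}
    return ([workdir / n for n in ("de_table.tsv", "de_genes.tsv", "de_summary.tsv",
                                   "top_differential.tsv")], counts)


def _stage_enrichment(config: PipelineConfig, workdir: Path, state: dict):
    if "de_genes" not in state:
        raise StageError("enrichment", "missing DE table (run the de stage first)")
    if "collection" not in state:
        raise StageError("enrichment", "missing gene-set collection (gmt input)")
    genes = state["de_genes"]
    universe = set(genes["gene_symbol"])
    de_up = set(genes.loc[genes["status"] == "up", "gene_symbol"])
    de_down = set(genes.loc[genes["status"] == "down", "gene_symbol"])
    outputs, counts = [], {}
    for mode, fname in (("GO", "go_enrichment.tsv"), ("pathway", "pathway_enrichment.tsv")):
        coll = state["collection"].of_category(mode)
        table = run_enrichment(coll, de_up, de_down, universe, mode=mode,
                               fdr_method=config.enrich_fdr_method,
                               p_threshold=config.p_threshold,
                               fdr_threshold=config.fdr_threshold)
        state[f"enrichment_{mode}"] = table
        write_table(table, workdir / fname)
        outputs.append(workdir / fname)
        sig = table[table["significant"]]
        counts[f"{mode}_significant_up"] = int((sig["direction"] == "up").sum())
        counts[f"{mode}_significant_down"] = int((sig["direction"] == "down").sum())
    go = state["enrichment_GO"]
    sig_terms = dict(zip(go.loc[go["significant"], "set_id"],
                         go.loc[go["significant"], "direction"]))
    ontology = None
    if config.ontology_tsv:
        ontology = pd.read_csv(config.ontology_tsv, sep="\t")
    tree = build_go_tree(sig_terms, ontology)
    write_graph_sif(tree, workdir / "go_tree.sif", workdir / "go_tree_nodes.tsv")
    outputs += [workdir / "go_tree.sif", workdir / "go_tree_nodes.tsv"]
    counts["go_tree_nodes"] = tree.number_of_nodes()
    return outputs, counts


def _stage_networks(config: PipelineConfig, workdir: Path, state: dict):
    if "de_genes" not in state:
        raise StageError("networks", "missing DE table (run the de stage first)")
    genes = state["de_genes"]
    outputs, counts = [], {}

    if "interactions" in state:
        gact = build_gene_act(state["interactions"], genes, config.hub_threshold)
        from .networks import kcore_decomposition
        kcore_decomposition(gact)
        write_graph_sif(gact, workdir / "gene_act.sif", workdir / "gene_act_nodes.tsv")
        write_table(pd.DataFrame({"hub": gact.graph["hubs"]}), workdir / "gene_act_hubs.tsv")
        outputs += [workdir / "gene_act.sif", workdir / "gene_act_nodes.tsv",
                    workdir / "gene_act_hubs.tsv"]
        counts["gene_act_nodes"] = gact.number_of_nodes()
        counts["gene_act_edges"] = gact.number_of_edges()
        counts["gene_act_hubs"] = len(gact.graph["hubs"])
        state["gene_act"] = gact

    if "enrichment_pathway" in state and "collection" in state:
        de_syms = set(genes.loc[genes["status"] != "ns", "gene_symbol"])
        pact = build_pathway_act(state["enrichment_pathway"],
                                 state["collection"], de_syms, config.min_shared)
        write_graph_sif(pact, workdir / "pathway_act.sif", workdir / "pathway_act_nodes.tsv")
        outputs += [workdir / "pathway_act.sif", workdir / "pathway_act_nodes.tsv"]
        counts["pathway_act_nodes"] = pact.number_of_nodes()
        counts["pathway_act_edges"] = pact.number_of_edges()
        state["pathway_act"] = pact

    de_subset = genes[genes["status"] != "ns"]
    for group in ("tumor", "normal"):
        g = build_coexpression(state["matrix"], group, de_subset,
                               config.r_threshold, config.coexpr_p_threshold)
        key = rank_key_genes(g, config.top_n)
        write_graph_sif(g, workdir / f"coexpr_{group}.sif",
                        workdir / f"coexpr_{group}_nodes.tsv")
        write_table(key, workdir / f"key_genes_{group}.tsv")
        outputs += [workdir / f"coexpr_{group}.sif",
                    workdir / f"coexpr_{group}_nodes.tsv",
                    workdir / f"key_genes_{group}.tsv"]
        counts[f"coexpr_{group}_edges"] = g.number_of_edges()
        state[f"coexpr_{group}"] = g
    return outputs, counts


def _stage_qpcr(config: PipelineConfig, workdir: Path, state: dict):
    if "qpcr_table" not in state or state["qpcr_table"] is None:
        raise StageError("qpcr", "missing qPCR Ct table")
    if "de" not in state:
        raise StageError("qpcr", "missing DE table (run the de stage first)")
    fc = fold_changes(state["qpcr_table"])
    write_table(fc, workdir / "qpcr_fold_changes.tsv")
    gene_fc = per_gene_fold_change(fc)
    array = state["de"].groupby("gene_symbol")["log2fc"].mean()
    report = concordance(gene_fc, array)
    write_table(report["per_gene"], workdir / "qpcr_concordance.tsv")
    counts = {"genes": report["n_genes"], "agreement": report["agreement"],
              "spearman_rho": report["spearman_rho"]}
    state["qpcr_report"] = report
    return ([workdir / "qpcr_fold_changes.tsv", workdir / "qpcr_concordance.tsv"], counts)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def summarize(manifest: RunManifest, workdir: str | Path | None = None, top_k: int = 10) -> str:
    """Human-readable run report with top-k excerpts of the result tables."""
    workdir = Path(workdir if workdir is not None else manifest.config["workdir"])
    lines = [f"# Pipeline run report (pairde {manifest.version})", ""]
    if not manifest.stages:
        lines.append("no stages run")
        return "\n".join(lines) + "\n"
    for stage, info in manifest.stages.items():
        lines.append(f"## {stage}")
        for key, val in info["counts"].items():
            lines.append(f"- {key}: {val}")
        lines.append("")
    excerpts = [
        ("Top differential genes", "top_differential.tsv"),
        ("GO enrichment", "go_enrichment.tsv"),
        ("Pathway enrichment", "pathway_enrichment.tsv"),
        ("Key genes (tumor co-expression)", "key_genes_tumor.tsv"),
        ("Key genes (normal co-expression)", "key_genes_normal.tsv"),
    ]
    for title, fname in excerpts:
        path = workdir / fname
        if not path.exists():
            continue
        df = pd.read_csv(path, sep="\t")
        lines.append(f"## {title} (top {min(top_k, len(df))})")
        lines.append(df.head(top_k).to_string(index=False))
        lines.append("")
    return "\n".join(lines) + "\n"
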