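"""On-disk formats and in-memory containers for the pipeline.

Everything the pipeline touches on disk is plain text: an expression TSV with
a companion design TSV, GMT gene-set collections, interaction/SIF tables, and
a ground-truth JSON for synthetic fixtures.  All writers are deterministic —
the same object always produces identical bytes (fixed column order, fixed
float formatting) — so run manifests can checksum stage outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: significant digits used in result tables (matches the precision of the
#: published per-gene tables); intermediate caches keep full precision.
TABLE_FLOAT_FMT = "%.6g"
FULL_FLOAT_FMT = "%.17g"

CONDITIONS = ("tumor", "normal")
BIOTYPES = ("mRNA", "lncRNA")


class FormatError(ValueError):
    """A file does not conform to its expected plain-text format."""


class DesignError(ValueError):
    """The sample design violates the paired-cohort contract."""


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExpressionMatrix:
    """Probe-by-sample log2 intensities plus probe and sample metadata.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, index = probe ids, columns = sample
        ids.  All values must be finite.
    probes
        DataFrame indexed by probe id with columns ``gene_symbol`` (may
        repeat across probes) and ``biotype`` (``mRNA`` or ``lncRNA``).
    design
        DataFrame indexed by sample id with columns ``condition`` (``tumor``
        or ``normal``) and ``pair_id`` (patient identifier).
    """

    values: pd.DataFrame
    probes: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate probe ids: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate sample ids in expression matrix")
        if not self.values.index.equals(self.probes.index):
            raise FormatError("probe metadata does not match value rows")
        if set(self.values.columns) != set(self.design.index):
            missing = set(self.values.columns) ^ set(self.design.index)
            raise DesignError(f"design rows do not match sample columns: {sorted(missing)[:5]}")
        # keep design in sample-column order
        self.design = self.design.loc[self.values.columns]
        bad_cond = set(self.design["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise DesignError(f"unknown conditions: {sorted(bad_cond)}")
        bad_bt = set(self.probes["biotype"]) - set(BIOTYPES)
        if bad_bt:
            raise FormatError(f"unknown biotypes: {sorted(bad_bt)}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            bad = self.values.index[~np.isfinite(arr).all(axis=1)]
            raise FormatError(f"non-finite values in probes: {list(bad[:5])}")

    # -- convenience accessors ------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    def samples_in(self, condition: str) -> list[str]:
        if condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
        return list(self.design.index[self.design["condition"] == condition])

    def complete_pairs(self) -> dict[str, tuple[str, str]]:
        """Map pair_id -> (tumor sample, normal sample), validating the design.

        Raises :class:`DesignError` naming the first pair that does not have
        exactly one tumor and one normal member.
        """
        pairs: dict[str, tuple[str, str]] = {}
        for pid, grp in self.design.groupby("pair_id", sort=True):
            tum = list(grp.index[grp["condition"] == "tumor"])
            nor = list(grp.index[grp["condition"] == "normal"])
            if len(tum) != 1 or len(nor) != 1:
                raise DesignError(
                    f"pair {pid!r} must have exactly one tumor and one normal sample "
                    f"(found {len(tum)} tumor, {len(nor)} normal)"
                )
            pairs[str(pid)] = (tum[0], nor[0])
        return pairs

    def subset_samples(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep = list(keep)
        return ExpressionMatrix(
            values=self.values[keep].copy(),
            probes=self.probes.copy(),
            design=self.design.loc[keep].copy(),
        )

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, probes=self.probes.copy(), design=self.design.copy())


def read_expression_tsv(path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV (probe_id, gene_symbol, biotype, samples...) and
    its companion design TSV (sample, condition, pair)."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_symbol": str, "biotype": str},
                     float_precision="round_trip")
    required = ["probe_id", "gene_symbol", "biotype"]
    if list(df.columns[:3]) != required:
        raise FormatError(f"expression TSV must start with columns {required}, got {list(df.columns[:3])}")
    sample_cols = list(df.columns[3:])
    if not sample_cols:
        raise FormatError("expression TSV has no sample columns")
    body = df[sample_cols]
    non_numeric = body.columns[~body.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(non_numeric):
        raise FormatError(f"non-numeric cells in sample columns: {list(non_numeric[:5])}")
    values = body.astype(float)
    values.index = pd.Index(df["probe_id"], name="probe_id")
    probes = df[["gene_symbol", "biotype"]].copy()
    probes.index = values.index
    design = pd.read_csv(design_path, sep="\t", dtype=str)
    if list(design.columns) != ["sample", "condition", "pair"]:
        raise FormatError(f"design TSV must have columns [sample, condition, pair], got {list(design.columns)}")
    design = design.rename(columns={"pair": "pair_id"}).set_index("sample")
    return ExpressionMatrix(values=values, probes=probes, design=design)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path, design_path: str | Path) -> None:
    out = matrix.probes.reset_index()[["probe_id", "gene_symbol", "biotype"]].copy()
    out = pd.concat([out, matrix.values.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, float_format=FULL_FLOAT_FMT, lineterminator="\n")
    des = matrix.design.reset_index()
    des.columns = ["sample", "condition", "pair"]
    des.to_csv(design_path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GeneSetCollection (GMT)
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GeneSet:
    name: str
    category: str  # "GO" or "pathway"
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.name!r} has an empty member list")


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets (GO terms or pathways) keyed by set id."""

    sets: dict[str, GeneSet]

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id].members

    def of_category(self, category: str) -> "GeneSetCollection":
        return GeneSetCollection({k: s for k, s in self.sets.items() if s.category == category})

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out.update(s.members)
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <TAB> description <TAB> member genes.

    The description field carries the category (``GO`` or ``pathway``);
    anything else defaults to ``GO``.  Duplicate members are dropped with a
    logged warning.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name, desc, *members = fields
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                logger.warning("%s:%d: set %s listed %d duplicate members; deduplicated",
                               path, lineno, name, len(members) - len(deduped))
            category = desc if desc in ("GO", "pathway") else "GO"
            sets[name] = GeneSet(name=name, category=category, members=tuple(deduped))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(collection.sets):
            s = collection.sets[sid]
            members = list(dict.fromkeys(s.members))
            fh.write("\t".join([sid, s.category, *members]) + "\n")


# ---------------------------------------------------------------------------
# InteractionTable (gene-gene interactions) and SIF graphs
# ---------------------------------------------------------------------------

RELATIONS = ("activation", "inhibition", "binding")
#: relations without direction, stored with lexicographically ordered endpoints
UNDIRECTED_RELATIONS = frozenset({"binding"})


@dataclasses.dataclass
class InteractionTable:
    """Rows of (gene_a, gene_b, relation, source) gene-gene interactions."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene_a", "gene_b", "relation", "source"]
        missing = [c for c in required if c not in self.rows.columns]
        if missing:
            raise FormatError(f"interaction table missing columns {missing}")
        self.rows = self.rows[required].reset_index(drop=True)
        loops = self.rows["gene_a"] == self.rows["gene_b"]
        if loops.any():
            raise FormatError(f"interaction table contains {int(loops.sum())} self-loop rows")
        # canonical endpoint order for undirected relations
        und = self.rows["relation"].isin(UNDIRECTED_RELATIONS)
        flip = und & (self.rows["gene_a"] > self.rows["gene_b"])
        a = self.rows.loc[flip, "gene_a"].copy()
        self.rows.loc[flip, "gene_a"] = self.rows.loc[flip, "gene_b"]
        self.rows.loc[flip, "gene_b"] = a

    def __len__(self) -> int:
        return len(self.rows)

    def degree(self, gene: str) -> int:
        """Number of distinct partners of *gene* (undirected view)."""
        touch = self.rows[(self.rows["gene_a"] == gene) | (self.rows["gene_b"] == gene)]
        partners = set(touch["gene_a"]).union(touch["gene_b"]) - {gene}
        return len(partners)


def read_interactions(path: str | Path) -> InteractionTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"interaction TSV needs >=3 columns, got {df.shape[1]}")
    if "source" not in df.columns:
        df["source"] = "unknown"
    loops = df[df.iloc[:, 0] == df.iloc[:, 1]]
    if len(loops):
        logger.warning("rejecting %d self-loop rows from %s", len(loops), path)
        df = df[df.iloc[:, 0] != df.iloc[:, 1]]
    df = df.rename(columns={df.columns[0]: "gene_a", df.columns[1]: "gene_b", df.columns[2]: "relation"})
    return InteractionTable(rows=df)


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    table.rows.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_graph_sif(graph: nx.Graph, sif_path: str | Path, attrs_path: str | Path | None = None) -> None:
    """Write a graph as SIF (``a <TAB> relation <TAB> b``) plus an optional
    node-attribute TSV (regulation, degree, core)."""
    with open(sif_path, "w") as fh:
        for a, b, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            rel = data.get("type", data.get("relation", "interaction"))
            fh.write(f"{a}\t{rel}\t{b}\n")
    if attrs_path is not None:
        rows = []
        for node in sorted(graph.nodes, key=str):
            d = graph.nodes[node]
            rows.append({
                "node": node,
                "kind": d.get("kind", "gene"),
                "regulation": d.get("regulation", ""),
                "degree": graph.degree(node),
                "core": d.get("core", ""),
            })
        pd.DataFrame(rows).to_csv(attrs_path, sep="\t", index=False, lineterminator="\n")


def read_sif(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: SIF line needs 3 fields, got {len(fields)}")
            a, rel, b = fields
            g.add_edge(a, b, type=rel)
    return g


# ---------------------------------------------------------------------------
# QPCRTable
# ---------------------------------------------------------------------------

CT_RANGE = (0.0, 45.0)


@dataclasses.dataclass
class QPCRTable:
    """Rows of (sample, condition, pair, gene, ct_target, ct_reference)."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample", "condition", "pair", "gene", "ct_target", "ct_reference"]
        missing = [c for c in required if c not in self.rows.columns]
        if missing:
            raise FormatError(f"qPCR table missing columns {missing}")
        self.rows = self.rows[required].reset_index(drop=True)
        for col in ("ct_target", "ct_reference"):
            ct = self.rows[col].astype(float)
            bad = (ct <= CT_RANGE[0]) | (ct > CT_RANGE[1])
            if bad.any():
                raise FormatError(f"{col} outside (0, 45] in {int(bad.sum())} rows")
            self.rows[col] = ct


def read_qpcr_tsv(path: str | Path) -> QPCRTable:
    return QPCRTable(rows=pd.read_csv(path, sep="\t"))


def write_qpcr_tsv(table: QPCRTable, path: str | Path) -> None:
    table.rows.to_csv(path, sep="\t", index=False, float_format=FULL_FLOAT_FMT, lineterminator="\n")


# ---------------------------------------------------------------------------
# Result tables and ground truth JSON
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, float_fmt: str = TABLE_FLOAT_FMT) -> None:
    """Deterministic result-table writer (fixed column order, 6 significant digits)."""
    df.to_csv(path, sep="\t", index=False, float_format=float_fmt, lineterminator="\n")


def write_json(obj: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Probe -> gene collapse
# ---------------------------------------------------------------------------

def collapse_by_symbol(de_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a probe-level result table to gene level.

    A symbol represented by several probes keeps the probe with the smallest
    differential-expression P; the rule is recorded in output metadata.
    Requires columns ``gene_symbol`` and ``p``.
    """
    for col in ("gene_symbol", "p"):
        if col not in de_table.columns:
            raise ValueError(f"collapse requires column {col!r}")
    idx = de_table.groupby("gene_symbol")["p"].idxmin()
    out = de_table.loc[idx].sort_values("gene_symbol").reset_index(drop=True)
    out.attrs["collapse_rule"] = "min-P probe per gene symbol"
    return out
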