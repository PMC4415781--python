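"""Synthetic paired tumor-normal expression fixtures with known planted structure.

The generator emulates a paired microarray cohort: each of ``n_pairs``
patients contributes one tumor and one adjacent-normal sample profiled on
the same probe set (mRNA and lncRNA biotypes).  Known structure is planted
so every downstream stage can be scored against ground truth:

* differential probes with a fixed |log2 fold change| added to the tumor
  member of every pair (sign randomized and recorded);
* gene sets over-sampling the planted differential genes, for enrichment
  recovery;
* co-expression modules driven by a shared latent factor in one tissue
  group only, calibrated to a target within-module correlation;
* interaction-network hubs given a fixed degree by construction.

All randomness flows from a single seed through named child streams, so a
fixture bundle is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    InteractionTable,
    QPCRTable,
    write_expression_tsv,
    write_gmt,
    write_interactions,
    write_json,
    write_qpcr_tsv,
)

_STREAMS = ("expression", "gene_sets", "interactions", "qpcr")


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic paired cohort.

    Defaults reproduce the study design the generator emulates: 26 tumor-
    normal pairs, 5000 probes (10% lncRNA), 200 planted differential probes
    at |log2FC| = 2 over measurement noise of SD 0.5, 200 gene sets of which
    3 are loaded with differential genes, and two 20-gene co-expression
    modules (one per tissue group) at target within-module correlation 0.85.
    """

    n_pairs: int = 26
    n_probes: int = 5000
    frac_lncrna: float = 0.1
    n_de: int = 200
    effect_log2fc: float = 2.0
    noise_sd: float = 0.5
    n_sets: int = 200
    set_size_range: tuple[int, int] = (10, 40)
    n_enriched_sets: int = 3
    n_modules: int = 2
    module_size: int = 20
    module_r: float = 0.85
    module_groups: tuple[str, ...] | None = None
    n_hubs: int = 3
    hub_degree: int = 30
    background_edges: int = 400
    patient_sd: float = 0.3
    baseline_mean_range: tuple[float, float] = (6.0, 14.0)
    baseline_sd_range: tuple[float, float] = (0.2, 1.0)
    ct_noise_sd: float = 0.3
    frac_dup_symbols: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first invalid parameter."""
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if not 0.0 <= self.frac_lncrna <= 1.0:
            raise ValueError("frac_lncrna must be in [0, 1]")
        if not 0 <= self.n_de <= self.n_probes:
            raise ValueError("n_de must satisfy 0 <= n_de <= n_probes")
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_sets < 0:
            raise ValueError("n_sets must be >= 0")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise ValueError("set_size_range must satisfy 1 <= lo <= hi")
        if hi > self.n_probes:
            raise ValueError("set_size_range exceeds the probe universe")
        if not 0 <= self.n_enriched_sets <= self.n_sets:
            raise ValueError("n_enriched_sets must satisfy 0 <= n_enriched_sets <= n_sets")
        if self.n_modules < 0:
            raise ValueError("n_modules must be >= 0")
        if self.n_modules and self.module_size < 2:
            raise ValueError("module_size must be >= 2")
        if self.n_modules * self.module_size > self.n_probes:
            raise ValueError("n_modules * module_size exceeds n_probes")
        if not 0.0 < self.module_r < 1.0:
            raise ValueError("module_r must be in (0, 1)")
        if self.module_groups is not None:
            if len(self.module_groups) != self.n_modules:
                raise ValueError("module_groups length must equal n_modules")
            if set(self.module_groups) - {"tumor", "normal"}:
                raise ValueError("module_groups entries must be 'tumor' or 'normal'")
        if self.n_hubs < 0:
            raise ValueError("n_hubs must be >= 0")
        if self.hub_degree < 1:
            raise ValueError("hub_degree must be >= 1")
        if self.background_edges < 0:
            raise ValueError("background_edges must be >= 0")
        if self.patient_sd < 0:
            raise ValueError("patient_sd must be >= 0")

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)

    def null(self) -> "SynthConfig":
        """A copy with no planted signal of any kind."""
        return self.replace(n_de=0, n_enriched_sets=0, n_modules=0, n_hubs=0)

    def _groups(self) -> tuple[str, ...]:
        if self.module_groups is not None:
            return self.module_groups
        return tuple("tumor" if i % 2 == 0 else "normal" for i in range(self.n_modules))


@dataclasses.dataclass
class GroundTruth:
    """What the generator planted; the scoring key for every stage."""

    de_effects: dict[str, float] = dataclasses.field(default_factory=dict)
    enriched_sets: dict[str, str] = dataclasses.field(default_factory=dict)  # set id -> direction
    modules: dict[str, dict] = dataclasses.field(default_factory=dict)  # id -> {probes, group}
    hub_genes: list[str] = dataclasses.field(default_factory=list)
    symbols: dict[str, str] = dataclasses.field(default_factory=dict)  # probe id -> gene symbol

    @property
    def de_probes(self) -> set[str]:
        return set(self.de_effects)

    def de_symbols(self, direction: str | None = None) -> set[str]:
        if direction not in (None, "up", "down"):
            raise ValueError("direction must be 'up', 'down' or None")
        out = set()
        for probe, eff in self.de_effects.items():
            if direction is None or (direction == "up") == (eff > 0):
                out.add(self.symbols[probe])
        return out

    def to_dict(self) -> dict:
        return {
            "de_effects": self.de_effects,
            "enriched_sets": self.enriched_sets,
            "modules": self.modules,
            "hub_genes": self.hub_genes,
            "symbols": self.symbols,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            de_effects=dict(d["de_effects"]),
            enriched_sets=dict(d["enriched_sets"]),
            modules={k: dict(v) for k, v in d["modules"].items()},
            hub_genes=list(d["hub_genes"]),
            symbols=dict(d["symbols"]),
        )


def _rng(config: SynthConfig, stream: str) -> np.random.Generator:
    idx = _STREAMS.index(stream)
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[idx])


def module_loading(module_r: float, noise_sd: float) -> float:
    """Latent-factor loading lambda with lambda^2/(lambda^2 + noise_sd^2) = module_r."""
    return noise_sd * math.sqrt(module_r / (1.0 - module_r))


def generate_paired_expression(config: SynthConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the paired cohort and return the matrix plus its ground truth.

    Per probe *g* and sample *s* of patient *p*:

    ``x[g, s] = mu_g + b[g, s] + a_p + de[g, s] + mod[g, s] + e[g, s]``

    with probe baseline ``mu_g ~ U(6, 14)``; per-sample biological deviation
    ``b ~ N(0, sd_g)`` with ``sd_g ~ U(0.2, 1)`` (suppressed for module
    probes so the latent-factor calibration is closed-form); patient effect
    ``a_p ~ N(0, patient_sd)`` shared by both members of a pair; planted
    effect ``±effect_log2fc`` on tumor samples of differential probes; the
    module latent term in the module's designated group only; and
    measurement noise ``e ~ N(0, noise_sd)``.
    """
    config.validate()
    rng = _rng(config, "expression")
    n, m = config.n_probes, 2 * config.n_pairs

    probe_ids = [f"PR{i:05d}" for i in range(n)]
    n_lnc = int(round(config.frac_lncrna * n))
    lnc_idx = rng.choice(n, size=n_lnc, replace=False) if n_lnc else np.array([], dtype=int)
    biotype = np.array(["mRNA"] * n, dtype=object)
    biotype[lnc_idx] = "lncRNA"
    symbols = np.array(
        [("LNC" if biotype[i] == "lncRNA" else "G") + f"{i:05d}" for i in range(n)],
        dtype=object,
    )
    # a small fraction of probes share a symbol with another probe of the same
    # biotype, to exercise the gene-level collapse rule downstream
    n_dup = int(round(config.frac_dup_symbols * n))
    dup_idx = rng.choice(n, size=min(n_dup, n), replace=False) if n_dup else np.array([], dtype=int)

    pair_ids = [f"P{i + 1:02d}" for i in range(config.n_pairs)]
    sample_ids = [f"{p}{suffix}" for p in pair_ids for suffix in ("T", "N")]
    condition = ["tumor", "normal"] * config.n_pairs
    sample_pair = np.repeat(np.arange(config.n_pairs), 2)
    tumor_cols = np.arange(0, m, 2)

    # planted differential probes, avoiding duplicate-symbol probes so that
    # probe-level truth maps 1:1 onto gene-level truth
    eligible = np.setdiff1d(np.arange(n), dup_idx)
    de_idx = rng.choice(eligible, size=config.n_de, replace=False) if config.n_de else np.array([], dtype=int)
    de_sign = rng.choice([-1.0, 1.0], size=config.n_de)

    # module probes: disjoint draws from the planted DE probes (the default
    # co-expression node set downstream), falling back to any probe when no
    # DE signal is planted
    need = config.n_modules * config.module_size
    module_pool = de_idx if need <= len(de_idx) else eligible
    mod_idx = rng.choice(module_pool, size=need, replace=False) if need else np.array([], dtype=int)
    modules = {
        f"MOD{k:02d}": mod_idx[k * config.module_size:(k + 1) * config.module_size]
        for k in range(config.n_modules)
    }
    groups = config._groups()

    base_mean = rng.uniform(*config.baseline_mean_range, size=n)
    base_sd = rng.uniform(*config.baseline_sd_range, size=n)
    base_sd[mod_idx] = 0.0  # module probes: latent + noise only (closed-form r)

    values = base_mean[:, None] + rng.normal(0.0, 1.0, size=(n, m)) * base_sd[:, None]
    patient = rng.normal(0.0, config.patient_sd, size=config.n_pairs)
    values += patient[sample_pair][None, :]
    if config.n_de:
        values[np.ix_(de_idx, tumor_cols)] += (de_sign * config.effect_log2fc)[:, None]
    lam = module_loading(config.module_r, config.noise_sd)
    for k, (mod_id, idx) in enumerate(modules.items()):
        group_cols = np.where(np.array(condition) == groups[k])[0]
        factor = rng.normal(0.0, 1.0, size=group_cols.size)
        values[np.ix_(idx, group_cols)] += lam * factor[None, :]
    values += rng.normal(0.0, config.noise_sd, size=(n, m))

    # assign duplicate symbols last so draws above are unaffected
    for i in dup_idx:
        same = np.where((biotype == biotype[i]) & (np.arange(n) != i))[0]
        if same.size:
            symbols[i] = symbols[rng.choice(same)]

    vdf = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    probes = pd.DataFrame({"gene_symbol": symbols, "biotype": biotype},
                          index=pd.Index(probe_ids, name="probe_id"))
    design = pd.DataFrame(
        {"condition": condition, "pair_id": np.array(pair_ids)[sample_pair]},
        index=pd.Index(sample_ids, name="sample"),
    )
    matrix = ExpressionMatrix(values=vdf, probes=probes, design=design)

    truth = GroundTruth(
        de_effects={probe_ids[i]: float(s * config.effect_log2fc)
                    for i, s in zip(de_idx, de_sign)},
        modules={mod_id: {"probes": [probe_ids[i] for i in idx], "group": groups[k]}
                 for k, (mod_id, idx) in enumerate(modules.items())},
        symbols={probe_ids[i]: str(symbols[i]) for i in range(n)},
    )
    return matrix, truth


def generate_gene_sets(truth: GroundTruth, config: SynthConfig) -> GeneSetCollection:
    """Draw ``n_sets`` gene sets over the fixture's symbol universe.

    The first ``n_enriched_sets`` sets over-sample planted differential
    genes — two thirds of their members come from one DE direction
    (alternating up/down), the rest from non-differential genes — and are
    recorded in ``truth.enriched_sets``.  Background sets sample uniformly.
    Set categories alternate GO/pathway so both enrichment modes have input.
    """
    config.validate()
    if not truth.symbols:
        raise ValueError("expression fixture must be generated before gene sets")
    rng = _rng(config, "gene_sets")
    universe = sorted(set(truth.symbols.values()))
    if config.set_size_range[1] > len(universe):
        raise ValueError("set_size_range exceeds the symbol universe")
    de_up = sorted(truth.de_symbols("up"))
    de_down = sorted(truth.de_symbols("down"))
    non_de = sorted(set(universe) - set(de_up) - set(de_down))

    sets: dict[str, GeneSet] = {}
    truth.enriched_sets = {}
    lo, hi = config.set_size_range
    for i in range(config.n_sets):
        sid = f"SET{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        category = "GO" if i % 2 == 0 else "pathway"
        if i < config.n_enriched_sets:
            direction = "up" if i % 2 == 0 else "down"
            pool = de_up if direction == "up" else de_down
            n_sig = min(max(math.ceil(2 * size / 3), (size + 1) // 2), len(pool))
            members = list(rng.choice(pool, size=n_sig, replace=False))
            members += list(rng.choice(non_de, size=size - n_sig, replace=False))
            truth.enriched_sets[sid] = direction
        else:
            members = list(rng.choice(universe, size=size, replace=False))
        sets[sid] = GeneSet(name=sid, category=category,
                            members=tuple(dict.fromkeys(members)))
    return GeneSetCollection(sets=sets)


def generate_interaction_table(truth: GroundTruth, config: SynthConfig) -> InteractionTable:
    """Emit a gene-gene interaction table with planted hubs.

    ``n_hubs`` planted hub genes are each wired to exactly ``hub_degree``
    distinct differential genes (so hub degree survives induction on the DE
    subgraph); background edges connect random non-hub genes.  No self-loops,
    no duplicate undirected pairs.
    """
    config.validate()
    if not truth.symbols:
        raise ValueError("expression fixture must be generated before interactions")
    rng = _rng(config, "interactions")
    relations = np.array(["activation", "inhibition", "binding"])
    de_syms = sorted(truth.de_symbols())
    universe = sorted(set(truth.symbols.values()))

    rows: list[tuple[str, str, str, str]] = []
    seen: set[frozenset] = set()
    n_hubs = min(config.n_hubs, len(de_syms))
    hubs = list(rng.choice(de_syms, size=n_hubs, replace=False)) if n_hubs else []
    truth.hub_genes = [str(h) for h in hubs]
    hub_set = set(truth.hub_genes)
    neighbor_pool = [g for g in de_syms if g not in hub_set]
    for h in truth.hub_genes:
        k = min(config.hub_degree, len(neighbor_pool))
        for nb in rng.choice(neighbor_pool, size=k, replace=False):
            rows.append((h, str(nb), str(rng.choice(relations)), "planted_hub"))
            seen.add(frozenset((h, str(nb))))

    non_hub = [g for g in universe if g not in hub_set]
    attempts = 0
    while len([r for r in rows if r[3] == "background"]) < config.background_edges:
        attempts += 1
        if attempts > 50 * max(config.background_edges, 1):
            break  # pool exhausted (tiny universes)
        a, b = rng.choice(non_hub, size=2, replace=False)
        key = frozenset((str(a), str(b)))
        if key in seen:
            continue
        seen.add(key)
        rows.append((str(a), str(b), str(rng.choice(relations)), "background"))

    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "relation", "source"])
    return InteractionTable(rows=df)


def generate_qpcr_table(
    truth: GroundTruth,
    config: SynthConfig,
    n_up: int = 6,
    n_down: int = 4,
) -> QPCRTable:
    """Simulate a qPCR validation panel from the planted effects.

    Target Ct values are built as reference Ct plus a gene-specific offset,
    minus the planted log2 effect in tumor samples (one PCR cycle per
    twofold change), with ``N(0, ct_noise_sd)`` measurement noise per well.
    """
    config.validate()
    if not truth.de_effects:
        raise ValueError("qPCR panel requires planted differential probes")
    rng = _rng(config, "qpcr")
    up = sorted(p for p, e in truth.de_effects.items() if e > 0)
    down = sorted(p for p, e in truth.de_effects.items() if e < 0)
    picks = list(rng.choice(up, size=min(n_up, len(up)), replace=False))
    picks += list(rng.choice(down, size=min(n_down, len(down)), replace=False))

    pair_ids = [f"P{i + 1:02d}" for i in range(config.n_pairs)]
    rows = []
    for probe in picks:
        gene = truth.symbols[probe]
        effect = truth.de_effects[probe]
        offset = rng.uniform(3.0, 10.0)
        for pid in pair_ids:
            for cond, suffix in (("tumor", "T"), ("normal", "N")):
                ct_ref = 15.0 + rng.normal(0.0, 0.1)
                shift = -effect if cond == "tumor" else 0.0
                ct_tgt = ct_ref + offset + shift + rng.normal(0.0, config.ct_noise_sd)
                rows.append({
                    "sample": f"{pid}{suffix}", "condition": cond, "pair": pid,
                    "gene": gene, "ct_target": ct_tgt, "ct_reference": ct_ref,
                })
    return QPCRTable(rows=pd.DataFrame(rows))


def generate_bundle(config: SynthConfig, outdir: str | Path | None = None):
    """Generate every fixture (expression, design, gene sets, interactions,
    qPCR, ground truth) and optionally write them under *outdir*.

    Returns ``(matrix, truth, collection, interactions, qpcr)``.
    """
    config.validate()
    matrix, truth = generate_paired_expression(config)
    collection = generate_gene_sets(truth, config)
    interactions = generate_interaction_table(truth, config)
    qpcr = generate_qpcr_table(truth, config) if truth.de_effects else None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_expression_tsv(matrix, outdir / "expression.tsv", outdir / "design.tsv")
        write_gmt(collection, outdir / "gene_sets.gmt")
        write_interactions(interactions, outdir / "interactions.tsv")
        if qpcr is not None:
            write_qpcr_tsv(qpcr, outdir / "qpcr.tsv")
        write_json(truth.to_dict(), outdir / "ground_truth.json")
    return matrix, truth, collection, interactions, qpcr
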