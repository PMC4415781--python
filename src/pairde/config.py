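"""Run configuration: one YAML document drives the whole pipeline.

Every stage threshold defaults to the published analysis values: fold
change > 2, P < 0.01, FDR < 0.01 for differential calling; Fisher P < 0.01
and dual-test FDR < 0.01 for enrichment; hub degree > 25; top 20 key genes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .synth import SynthConfig

STAGES = ("simulate", "normalize", "qc", "de", "enrichment", "networks", "qpcr")


@dataclasses.dataclass
class PipelineConfig:
    workdir: str = "pairde_run"
    seed: int = 0
    stages: dict[str, bool] = dataclasses.field(
        default_factory=lambda: {s: True for s in STAGES})

    # inputs (used when the simulate stage is disabled)
    expression_tsv: str | None = None
    design_tsv: str | None = None
    gmt: str | None = None
    interactions_tsv: str | None = None
    qpcr_tsv: str | None = None
    ontology_tsv: str | None = None  # child->parent edges for the GO tree

    # synthetic-data overrides (simulate stage)
    synth: dict = dataclasses.field(default_factory=dict)

    # stage parameters (defaults = published thresholds)
    qc_alpha: float = 0.001
    fc_threshold: float = 2.0
    p_threshold: float = 0.01
    fdr_threshold: float = 0.01
    # dual-test 1-Nk/T saturates at 1 whenever the top-ranked set's exact
    # Fisher P exceeds its asymptotic chi-square P (routine at strong
    # enrichment), so the orchestrated default is BH; 'paper' stays available
    enrich_fdr_method: str = "bh"
    r_threshold: float = 0.8
    coexpr_p_threshold: float = 0.01
    hub_threshold: int = 25
    min_shared: int = 3
    top_n: int = 20

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        for name in ("fc_threshold", "p_threshold", "fdr_threshold",
                     "coexpr_p_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.qc_alpha < 1.0:
            raise ValueError("qc_alpha must be in [0, 1)")
        if not 0.0 < self.r_threshold <= 1.0:
            raise ValueError("r_threshold must be in (0, 1]")
        if self.enrich_fdr_method not in ("paper", "bh"):
            raise ValueError("enrich_fdr_method must be 'paper' or 'bh'")
        if self.hub_threshold < 0 or self.min_shared < 1 or self.top_n < 1:
            raise ValueError("hub_threshold >= 0, min_shared >= 1, top_n >= 1 required")
        if not self.stages["simulate"]:
            for field in ("expression_tsv", "design_tsv"):
                path = getattr(self, field)
                if any(self.stages[s] for s in STAGES[1:]) and path is None:
                    raise ValueError(f"{field} is required when the simulate stage is disabled")
                if path is not None and not Path(path).exists():
                    raise ValueError(f"{field} does not exist: {path}")

    def synth_config(self) -> SynthConfig:
        cfg = SynthConfig(seed=self.seed, **{k: tuple(v) if isinstance(v, list) else v
                                             for k, v in self.synth.items()})
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
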