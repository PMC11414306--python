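"""Pipeline configuration: one validated record of every tunable knob."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Mapping

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0
    # cohort simulation
    n_per_group: int = 10
    n_genes: int = 2000
    n_leaf_taxa: int = 30
    # expression prep
    min_cpm: float = 1.0
    min_fraction: float = 0.5
    de_fraction: float = 0.05
    # microbiome prep
    taxa_transform: str = "log10"  # log10 | clr
    taxa_pseudocount: float = 1e-6
    min_prevalence: float = 0.0  # fraction of samples a taxon must be present in
    # network
    pcit_delta: float = 1e-8
    alpha: float = 0.05
    # downstream
    stepwise_target_r2: float = 0.90
    stepwise_tol: float = 1e-6
    cluster_linkage: str = "average"  # average | complete
    export_formats: tuple[str, ...] = ("edge-tsv", "sif", "graphml")

    def __post_init__(self) -> None:
        checks = [
            (self.n_per_group >= 2, "n_per_group must be >= 2"),
            (self.n_genes >= 100, "n_genes must be >= 100"),
            (self.n_leaf_taxa >= 4, "n_leaf_taxa must be >= 4"),
            (self.min_cpm >= 0, "min_cpm must be >= 0"),
            (0 < self.min_fraction <= 1, "min_fraction must be in (0, 1]"),
            (0 < self.de_fraction < 1, "de_fraction must be in (0, 1)"),
            (self.taxa_transform in ("log10", "clr"), "taxa_transform must be log10 or clr"),
            (self.taxa_pseudocount > 0, "taxa_pseudocount must be > 0"),
            (0 <= self.min_prevalence <= 1, "min_prevalence must be in [0, 1]"),
            (self.pcit_delta > 0, "pcit_delta must be > 0"),
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (0 < self.stepwise_target_r2 <= 1, "stepwise_target_r2 must be in (0, 1]"),
            (self.stepwise_tol >= 0, "stepwise_tol must be >= 0"),
            (self.cluster_linkage in ("average", "complete"), "cluster_linkage must be average or complete"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)
        unknown = set(self.export_formats) - {"edge-tsv", "sif", "graphml"}
        if unknown:
            raise ValueError(f"unknown export format(s): {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        if "export_formats" in d:
            d["export_formats"] = tuple(d["export_formats"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["export_formats"] = list(self.export_formats)
        return d
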