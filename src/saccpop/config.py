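"""Pipeline configuration: every stage threshold with its default.

The configuration is a flat dataclass; YAML files override fields by
name and unknown keys are rejected so that a typo cannot silently fall
back to a default.  The resolved configuration is echoed verbatim into
the run manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "saccpop_out"
    stages: tuple[str, ...] = ("simulate", "call", "stats", "phylo",
                               "karyotype", "scan")

    # synthgen
    n_wild: int = 10
    n_domesticated: int = 8
    genome_scale: float = 1.0
    mean_depth: float = 50.0
    error_rate: float = 0.002
    flow_noise_sd: float = 0.05

    # snpcall
    min_depth: int = 15
    max_depth_factor: float = 4.0
    hom_fraction: float = 0.80
    het_fraction: float = 0.20
    max_site_missing: float = 0.10

    # popstats
    min_group_coverage: float = 0.80
    partition_min_nonmissing: float = 0.75
    partition_mode: str = "ambiguity"

    # rrhs
    replicates: int = 100

    # karyotype
    frame_size: int = 1000
    tails: str = "default"        # "default" | "fit"
    cnv_test: str = "wilcoxon"    # "wilcoxon" | "ttest"
    cnv_alpha: float = 0.01

    # introscan
    scan_window: int = 1000
    scan_step: int = 500
    stage1_identity: float = 95.0
    stage1_min_len: int = 1000
    final_identity: float = 93.0
    final_min_len: int = 1500

    def validate(self) -> None:
        if self.min_depth < 0 or self.mean_depth < 1:
            raise ValueError("depth thresholds must be non-negative")
        if not (0 <= self.error_rate <= 0.05):
            raise ValueError("error rate out of range")
        if not (0 < self.hom_fraction <= 1 and 0 < self.het_fraction <= 0.5):
            raise ValueError("allele-fraction thresholds out of range")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.tails not in ("default", "fit"):
            raise ValueError("tails must be 'default' or 'fit'")
        if self.cnv_test not in ("wilcoxon", "ttest"):
            raise ValueError("cnv_test must be 'wilcoxon' or 'ttest'")
        if self.partition_mode not in ("ambiguity", "biallelic"):
            raise ValueError("partition_mode must be ambiguity|biallelic")
        unknown = set(self.stages) - {"simulate", "call", "stats", "phylo",
                                      "karyotype", "scan"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "stages" in data:
            data = {**data, "stages": tuple(data["stages"])}
        cfg = cls(**data)
        cfg.validate()
        return cfg
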