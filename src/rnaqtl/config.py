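"""Pipeline configuration with the study's default thresholds."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All stage thresholds, serialized with every output for provenance."""

    # sample QC
    het_low: float = 0.2
    het_high: float = 0.4
    het_min_maf: float = 0.05
    het_min_depth: int = 10
    outlier_cutoff: float = 4.0
    outlier_component: int = 0
    # duplicate detection
    dup_cutoff: float = 0.78
    dedup_min_dr2: float = 0.95
    dedup_min_maf: float = 0.05
    dedup_min_call_rate: float = 0.95
    prune_window: int = 1000
    prune_step: int = 5
    prune_r2: float = 0.2
    # eQTL mapping
    cis_window_bp: int = 250_000
    eqtl_min_dr2: float = 0.8
    eqtl_min_maf: float = 0.05
    eqtl_min_n: int = 30
    n_perm: int = 10
    fdr: float = 0.05
    n_expression_pcs: int | None = None  # None -> min(100, n_samples // 10)
    n_genotype_pcs: int = 4
    # ASE
    ase_min_het_samples: int = 5
    ase_min_reads_per_allele: int = 10
    ase_min_allele_frac: float = 0.02
    ase_min_gq: float = 30.0
    ase_min_mappability: float = 1.0
    # global
    seed: int = 0

    def validate(self) -> None:
        if not self.het_low < self.het_high:
            raise ValueError("het_low must be below het_high")
        for name in ("dup_cutoff", "fdr", "ase_min_allele_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_perm < 0 or self.prune_window < 2 or self.prune_step < 1:
            raise ValueError("invalid permutation/pruning settings")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
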