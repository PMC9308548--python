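"""Pipeline configuration.

All thresholds used by the analysis stages live in a single flat
:class:`PipelineConfig`.  A config file is a flat YAML mapping; every CLI
flag overrides its config key, so one artifact fully determines a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


# fields that must lie strictly inside (0, 1)
_UNIT_INTERVAL_FIELDS = (
    "stage1_p",
    "stage1_delta",
    "stage2_p",
    "stage2_delta",
    "stage2_q",
    "enrich_fdr",
    "delta_corr_p",
    "ego_top_fraction",
    "split_train_fraction",
)

# integer fields that must be >= 1
_POSITIVE_INT_FIELDS = ("enrich_min_count", "cv_folds")


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and switches for every pipeline stage.

    Default thresholds: stage-1 differential calling
    at p < 0.05 and mean-difference A > 0.05; stage-2 refinement at
    methylation score > 50, p < 0.001, |t| > 3, A >= 0.17 and BH q < 0.05;
    enrichment significance at FDR < 0.01 with overlap > 10 genes;
    correlation gating at Pearson p = 0.05; top 30% ego genes; 6:4
    stratified train/test split with 5-fold cross-validation.
    """

    stage1_p: float = 0.05
    stage1_delta: float = 0.05
    stage2_p: float = 0.001
    stage2_tstat: float = 3.0
    stage2_score: float = 50.0
    stage2_delta: float = 0.17
    stage2_q: float = 0.05
    enrich_fdr: float = 0.01
    enrich_min_count: int = 10
    delta_corr_p: float = 0.05
    ego_top_fraction: float = 0.30
    split_train_fraction: float = 0.6
    cv_folds: int = 5
    rng_seed: int = 0

    # interpretation switches (documented deviations / alternatives)
    maf_rule: str = "as_printed"  # {"as_printed": remove MAF<0.05, "conventional": remove MAF>=0.05}
    ttest: str = "welch"  # {"welch", "pooled"}
    gene_p_combine: str = "min"  # {"min", "fisher"}
    node_score: str = "neglog10p"  # {"neglog10p", "beta_mean"}
    standardize: bool = True
    seed_genes: tuple = ()

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in _UNIT_INTERVAL_FIELDS:
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name}={v!r} must lie in (0, 1)")
        for name in _POSITIVE_INT_FIELDS:
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise ConfigError(f"{name}={v!r} must be an integer >= 1")
        if self.stage2_tstat <= 0:
            raise ConfigError("stage2_tstat must be positive")
        if not (0.0 < self.stage2_score < 100.0):
            raise ConfigError("stage2_score must lie in (0, 100)")
        if not isinstance(self.rng_seed, int):
            raise ConfigError("rng_seed must be an integer")
        if self.maf_rule not in ("as_printed", "conventional"):
            raise ConfigError(f"unknown maf_rule {self.maf_rule!r}")
        if self.ttest not in ("welch", "pooled"):
            raise ConfigError(f"unknown ttest {self.ttest!r}")
        if self.gene_p_combine not in ("min", "fisher"):
            raise ConfigError(f"unknown gene_p_combine {self.gene_p_combine!r}")
        if self.node_score not in ("neglog10p", "beta_mean"):
            raise ConfigError(f"unknown node_score {self.node_score!r}")

    def replace(self, **changes: Any) -> "PipelineConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        if "seed_genes" in changes and changes["seed_genes"] is not None:
            changes["seed_genes"] = tuple(changes["seed_genes"])
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a flat YAML key-value file."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed_genes" in raw and raw["seed_genes"] is not None:
            raw["seed_genes"] = tuple(raw["seed_genes"])
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["seed_genes"] = list(d["seed_genes"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def stage_seed(self, stage_index: int) -> int:
        """Deterministic per-stage child seed derived from the master seed."""
        return int(self.rng_seed) * 1000 + int(stage_index)
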