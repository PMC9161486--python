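"""Structured pipeline configuration (YAML, fully defaulted, strict keys)."""

from __future__ import annotations

import hashlib
import json

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError


class ConfigError(ValueError):
    """Raised when a configuration does not validate."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ThresholdsCfg(_Strict):
    log2fc_cut: float = 2.0
    padj_cut: float = 0.05
    protein_p_cut: float = 0.05
    rpm_cut: float = 15.0


class SeedPolicyCfg(_Strict):
    seed_start: int = 2
    seed_end: int = 8
    tol3: int = 3


class DuplexCfg(_Strict):
    match: float = 5.0
    gu_wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    seed_scale: float = 2.0
    score_threshold: float = 80.0
    min_site_type: str = "7mer_A1"


class GseaCfg(_Strict):
    n_perm: int = 1000
    weight_p: float = 1.0
    mode: str = "preranked_setperm"
    min_set_size: int = 5


class SimulateCfg(_Strict):
    n_reads: int = 10000
    offset5_probs: dict[int, float] = Field(default_factory=lambda: {0: 0.5, 1: 0.3, 2: 0.2})
    offset3_probs: dict[int, float] = Field(
        default_factory=lambda: {-1: 0.2, 0: 0.6, 1: 0.2}
    )
    n_tumor: int = 20
    n_normal: int = 20
    n_features: int = 500


class InputsCfg(_Strict):
    reads_fastq: str | None = None
    premirna_fasta: str | None = None
    arm_table: str | None = None
    arm_id: str | None = None
    counts_tsv: str | None = None
    design_tsv: str | None = None
    expression_tsv: str | None = None
    gene_sets_gmt: str | None = None
    activity_set: str | None = None
    utr_fasta: str | None = None
    mirna_seq: str | None = None
    mirna_id: str | None = None
    offset5: int = 0
    ranked_rnk: str | None = None
    phenotype_tsv: str | None = None


class PipelineConfig(_Strict):
    outdir: str = "seedshift_out"
    seed: int = 0
    thresholds: ThresholdsCfg = Field(default_factory=ThresholdsCfg)
    seed_policy: SeedPolicyCfg = Field(default_factory=SeedPolicyCfg)
    duplex: DuplexCfg = Field(default_factory=DuplexCfg)
    gsea: GseaCfg = Field(default_factory=GseaCfg)
    simulate: SimulateCfg = Field(default_factory=SimulateCfg)
    inputs: InputsCfg = Field(default_factory=InputsCfg)

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def validate_config(raw_text: str) -> PipelineConfig:
    """Parse YAML text into a fully-defaulted, type-checked config.

    Unknown keys, type mismatches and non-positive thresholds are
    rejected with a message naming the offending field.
    """
    try:
        data = yaml.safe_load(raw_text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"config is not valid YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping at the top level")
    try:
        cfg = PipelineConfig.model_validate(data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigError(f"invalid config field {loc!r}: {first['msg']}") from exc
    th = cfg.thresholds
    for name in ("log2fc_cut", "padj_cut", "protein_p_cut", "rpm_cut"):
        if getattr(th, name) <= 0:
            raise ConfigError(f"invalid config field 'thresholds.{name}': must be > 0")
    if cfg.gsea.n_perm < 100:
        raise ConfigError("invalid config field 'gsea.n_perm': must be >= 100")
    return cfg
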