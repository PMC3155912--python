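"""Flat pipeline configuration with validated defaults.

Defaults follow the analysis constants of the study design this pipeline
automates: q < 0.05 with |log2 FC| > 0.6 for differential expression,
smoothing over 10 probes per side, CBS at alpha = 0.05, gene copy scores
from >= 3 probes, CNA gene-set thresholds of +/-0.3 (log10) with
top/bottom-quartile expression gates, and the lowest-quartile expression
filter.  Every key can be set from a YAML file and overridden per-run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # global
    seed: int = 0
    threads: int = 1  # accepted for symmetry; all hot loops are vectorized,
    #                   results never depend on it

    # synthetic data
    n_chrom: int = 5
    genes_per_chrom: int = 600
    probes_per_chrom: int = 2000
    n_cna_segments: int = 8
    probe_noise_sd: float = 0.08
    outlier_rate: float = 0.002
    outlier_sd: float = 5.0
    n_treated: int = 5
    n_naive: int = 6
    base_mean: float = 7.0
    base_sd: float = 1.5
    dosage_beta: float = 1.0
    treatment_effect: float = 0.6
    responder_fraction: float = 0.8
    background_de_fraction: float = 0.02
    expr_noise_sd: float = 0.25
    outlier_sample: bool = False

    # expression stage
    group_a: str = "treated"
    group_b: str = "naive"
    discard_fraction: float = 0.25
    q_max: float = 0.05
    min_abs_log2_fc: float = 0.6
    cluster_top_fraction: float = 0.75
    log2_transform: bool = False

    # segmentation stage
    smooth_region: int = 10
    smooth_outlier_sd: float = 4.0
    smooth_shrink_sd: float = 2.0
    cbs_alpha: float = 0.05
    cbs_n_perm: int = 1000
    min_probes: int = 3

    # integration stage
    gain_threshold: float = 0.3
    loss_threshold: float = -0.3
    high_expr_quantile: float = 0.75
    low_expr_quantile: float = 0.25
    gsea_n_perm: int = 1000
    gsea_mode: str = "gene_set"
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    weight_exponent: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            (self.seed >= 0, "seed must be >= 0"),
            (0 < self.discard_fraction < 1 or self.discard_fraction == 0,
             "discard_fraction must be in [0, 1)"),
            (self.q_max > 0, "q_max must be positive"),
            (self.min_abs_log2_fc > 0, "min_abs_log2_fc must be positive"),
            (0 < self.cbs_alpha < 1, "cbs_alpha must be in (0, 1)"),
            (self.cbs_n_perm > 0, "cbs_n_perm must be positive"),
            (self.smooth_region >= 1, "smooth_region must be >= 1"),
            (self.min_probes >= 1, "min_probes must be >= 1"),
            (self.loss_threshold < 0 < self.gain_threshold,
             "need loss_threshold < 0 < gain_threshold"),
            (0 < self.low_expr_quantile < 1, "low_expr_quantile in (0, 1)"),
            (0 < self.high_expr_quantile < 1, "high_expr_quantile in (0, 1)"),
            (self.gsea_mode in ("gene_set", "phenotype"),
             "gsea_mode must be gene_set or phenotype"),
            (0 <= self.responder_fraction <= 1,
             "responder_fraction must be in [0, 1]"),
        ]
        for ok, message in checks:
            if not ok:
                raise ValueError(message)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
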