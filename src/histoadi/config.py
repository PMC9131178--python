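"""Pipeline configuration: defaults, parsing, validation.

Defaults follow the published workflow: 224-px tiles at 0.5 microns per
pixel, background threshold 200, cutpoint stratification with minprop
0.1, ssGSEA weight 0.25, 1,000 permutations. Unknown keys and
out-of-range values are rejected with the offending field named.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # paths (None disables the dependent stage)
    slides_dir: str | None = None
    survival_table: str | None = None
    expression: str | None = None
    gene_sets: str | None = None
    out_dir: str = "histoadi_out"
    # tiling
    tile_px: int = 224
    target_mpp: float = 0.5
    background_threshold: float = 200.0
    # classification
    model_path: str | None = None  # load instead of training
    train_tiles_per_class: int = 60  # synthetic training size for the reference model
    # scoring
    exclude_model_background: bool = False
    # survival
    stratification: str = "cutpoint"  # or "median"
    minprop: float = 0.1
    # enrichment
    ssgsea_alpha: float = 0.25
    n_permutations: int = 1000
    group_test: str = "welch"  # or "mannwhitney"
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tile_px < 1:
            raise ValueError("tile_px must be >= 1")
        if self.target_mpp <= 0:
            raise ValueError("target_mpp must be > 0")
        if not 0 <= self.background_threshold <= 255:
            raise ValueError("background_threshold must lie in [0, 255]")
        if self.train_tiles_per_class < 20:
            raise ValueError("train_tiles_per_class must be >= 20")
        if self.stratification not in ("cutpoint", "median"):
            raise ValueError("stratification must be 'cutpoint' or 'median'")
        if not 0 < self.minprop < 0.5:
            raise ValueError("minprop must be in (0, 0.5)")
        if self.ssgsea_alpha < 0:
            raise ValueError("ssgsea_alpha must be >= 0")
        if self.n_permutations < 10:
            raise ValueError("n_permutations must be >= 10")
        if self.group_test not in ("welch", "mannwhitney"):
            raise ValueError("group_test must be 'welch' or 'mannwhitney'")
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must be a non-negative 31-bit integer")


def validate_config(raw: dict | None) -> PipelineConfig:
    """Build a config from a mapping, rejecting unknown keys."""
    raw = dict(raw or {})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Parse a YAML config file; an absent path gives all defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    return validate_config(raw)


def config_as_dict(config: PipelineConfig) -> dict:
    return {f.name: getattr(config, f.name) for f in fields(config)}
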