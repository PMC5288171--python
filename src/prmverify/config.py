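"""Pipeline configuration: every tunable threshold in one place.

Defaults reproduce the published rules: cos(theta) strictly above 0.98
for both labels, at least 4 product ions, removal of peptides below the
LOD in more than 50% of samples, significance at BH-adjusted p < 0.05
with fold change > 3, and sensitivity reported at 95% specificity.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    cos_threshold: float = 0.98
    min_ions: int = 4
    interference_share_factor: float = 1.5
    lod_criterion: float = 0.0  # summed light area below this is below-LOD
    lod_floor: float = 0.0  # censoring floor used by the background rule
    lod_removal_fraction: float = 0.5
    fc_threshold: float = 3.0
    alpha: float = 0.05
    fixed_specificity: float = 0.95
    fc_definition: str = "median_ratio"
    blood_slope_tolerance: float = 0.0
    tic_outlier_k: float = 5.0
    sibling_log_scale: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cos_threshold < 1:
            raise ValueError("cos_threshold must lie in (0, 1)")
        if self.min_ions < 1:
            raise ValueError("min_ions must be >= 1")
        if self.interference_share_factor <= 1:
            raise ValueError("interference_share_factor must exceed 1")
        if self.lod_criterion < 0 or self.lod_floor < 0:
            raise ValueError("LOD levels must be non-negative")
        if not 0 <= self.lod_removal_fraction <= 1:
            raise ValueError("lod_removal_fraction must lie in [0, 1]")
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.fixed_specificity <= 1:
            raise ValueError("fixed_specificity must lie in (0, 1]")
        if self.fc_definition not in ("median_ratio", "mean_ratio"):
            raise ValueError("fc_definition must be median_ratio or mean_ratio")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
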