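"""Run configuration: one structured YAML file covering every stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    # image scale
    pixel_size_um: float = 0.5
    # segmentation
    smooth_sigma_um: float = 1.0
    threshold: str | float = "otsu"
    min_area_um2: float = 50.0
    max_hole_area_um2: float = 100.0
    opening_radius_um: float = 0.0
    # nuclei
    nucleus_radius_um: float = 4.0
    floor_quantile: float = 0.99
    separation_factor: float = 1.0
    # morphology
    connectivity: int = 2
    closing_radius_um: float = 100.0
    min_core_area_um2: float = 5e5
    front_width_um: float = 500.0
    core_excludes_inner_front: bool = False
    # fields of view
    fov_stride_um: float | None = None
    # survival
    min_prevalence: float = 0.25
    m_hypotheses: int = 7
    min_node_size: int = 8
    # misc
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "nucleus_radius_um", "closing_radius_um",
                     "front_width_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.min_prevalence < 0.5:
            raise ValueError("min_prevalence must lie in (0, 0.5)")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
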