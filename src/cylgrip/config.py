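"""Pipeline configuration with lossless YAML/JSON round-trip."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Everything a reproducible simulate/measure/analyze run needs.

    Units are millimetres and degrees throughout.  ``seed`` drives every
    source of randomness; no stage draws from ambient entropy.
    """

    seed: int
    diameters_mm: list = field(default_factory=lambda: [10.0, 60.0, 120.0])
    hand_length_mm: float = 185.8
    contact_tolerance_mm: float = 0.5
    # landmark-picking noise
    n_ring_points: int = 8
    angular_jitter_deg: float = 10.0
    radial_noise_mm: float = 0.2
    # cohort simulation
    n_subjects: int = 10
    subject_sd_fraction: float = 0.5
    # analysis switches
    center_estimator: str = "centroid"  # or "circle_fit"
    posthoc_method: str = "paired"  # or "pooled"
    alpha: float = 0.05
    mesh_format: str = "ply"  # or "stl"
    mesh_ascii: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory for any stochastic run")
        self.seed = int(self.seed)
        self.diameters_mm = [float(d) for d in self.diameters_mm]
        if self.center_estimator not in ("centroid", "circle_fit"):
            raise ValueError(f"unknown estimator {self.center_estimator!r}")
        if self.posthoc_method not in ("paired", "pooled"):
            raise ValueError(f"unknown post-hoc method {self.posthoc_method!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
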