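"""Run configuration: validated settings for an analysis run.

A config file (YAML or JSON) maps directly onto :class:`AnalysisConfig`;
unknown keys are rejected before any computation.  The configuration hash —
embedded in every output file for provenance — covers the scientific settings
only, not input/output paths, so identical analyses written to different
locations hash identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


#: keys excluded from the provenance hash
_NON_SCIENTIFIC_KEYS = {"input_path", "output_dir", "log_level"}


@dataclass
class AnalysisConfig:
    """Settings for one analysis run (video pose stream or marker stream)."""

    input_path: str = ""
    input_kind: str = "openpose"  # 'openpose' | 'markers'
    output_dir: str = "analysis"
    frame_rate: float = 25.0
    camera_side: str = "left"
    image_width: int = 960
    image_height: int = 540
    confidence_threshold: float = 0.0
    same_leg_eps_px: float = 5.0
    max_gap_frames: int = 2
    cutoff_hz: float = 5.0
    filter_order: int = 4
    reference_distance_m: float = 6.30
    reference_pixel_length: float | None = None
    min_period_s: float = 0.4
    prominence_frac: float = 0.25
    boundary_margin_s: float | None = None
    exclude_boundary: bool = True
    n_cycle_samples: int = 101
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.input_kind not in ("openpose", "markers"):
            raise ConfigError(f"input_kind must be 'openpose' or 'markers', got {self.input_kind!r}")
        if self.camera_side not in ("left", "right"):
            raise ConfigError(f"camera_side must be 'left' or 'right', got {self.camera_side!r}")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        if self.n_cycle_samples < 2:
            raise ConfigError("n_cycle_samples must be at least 2")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = {
            k: v for k, v in self.to_dict().items() if k not in _NON_SCIENTIFIC_KEYS
        }
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()
        return digest[:12]


__all__ = ["AnalysisConfig", "ConfigError"]
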