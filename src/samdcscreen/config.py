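"""Pipeline configuration: defaults, YAML round-trip, config hashing.

All defaults equal the published protocol constants: score cut -7.5,
cluster cut 3.0 A at 75 %, score density cut -0.28, pocket-out maximum
30 %, dAU window 0 -> 5 min, 100 uM screening concentration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .pose_triage import FilterThresholds

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclasses.dataclass
class PipelineConfig:
    thresholds: FilterThresholds = dataclasses.field(default_factory=FilterThresholds)
    dau_t0_min: float = 0.0
    dau_t1_min: float = 5.0
    rate_window_min: float = 1.0
    screen_concentration_uM: float = 100.0
    recapture_rmsd_cut: float = 2.0
    recapture_top_n: int = 5
    similarity_cut: float = 1.0
    seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = FilterThresholds(**d["thresholds"])
        return cls(**d)

    def config_hash(self) -> str:
        """Stable short hash of the configuration, for run logging."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))
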