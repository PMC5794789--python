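"""Run-time configuration for the pipeline tunables, loadable from YAML.

Only parameters a user might realistically retune are exposed; everything
defaults to the values the method was designed with.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .features import DEFAULT_FEATURE_NAMES


@dataclass
class PipelineConfig:
    # stage-1 pre-processing
    band_lo_hz: float = 140.0
    band_hi_hz: float = 22000.0
    frame_len_s: float = 0.04
    step_s: float = 0.02
    # features / classifier
    feature_names: list[str] = field(
        default_factory=lambda: list(DEFAULT_FEATURE_NAMES))
    ridge: float = 1e-6
    median_order: int = 5
    min_event_frames: int = 5
    noise_energy_fraction: float = 0.4
    # flow estimation
    flow_band_lo_hz: float = 200.0
    flow_band_hi_hz: float = 5000.0
    flow_frame_len_s: float = 0.05
    flow_step_s: float = 0.025
    power_gamma: float = 0.3183
    power_delta: float = 7.5061
    # technique rules
    pifr_too_fast_lmin: float = 90.0

    @classmethod
    def load(cls, path: str | Path | None = None) -> "PipelineConfig":
        cfg = cls()
        if path is None:
            return cfg
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - set(asdict(cfg))
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key, value in doc.items():
            setattr(cfg, key, value)
        return cfg

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
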