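"""Pipeline configuration.

All tunable knobs of the analysis live here as plain dataclasses so a run is a
pure function of (config, seed).  Defaults: 512-sample Hann window / 128-sample
hop at 250 kHz (~488 Hz bins, ~0.512 ms hop), 30-110 kHz analysis band, 10 dB
detection threshold, 2 s bout gap, 5% transition-edge threshold, and an initial
k of 10 for call typing (one cluster is expected to absorb noise and is removed
to leave 9 call types).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class StftParams:
    window_length: int = 512       # samples
    hop: int = 128                 # samples
    window: str = "hann"

    def validate(self) -> None:
        if self.window_length < 64:
            raise ValueError(f"window_length must be >= 64 samples, got {self.window_length}")
        if not 0 < self.hop <= self.window_length:
            raise ValueError(f"hop must be in (0, window_length], got {self.hop}")


@dataclass
class DetectionParams:
    band_low_hz: float = 30_000.0
    band_high_hz: float = 110_000.0
    snr_threshold_db: float = 10.0
    min_duration_s: float = 0.005
    merge_gap_s: float = 0.003
    smooth_frames: int = 5         # moving-average width for the voicing test

    def validate(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        for name in ("snr_threshold_db", "min_duration_s", "merge_gap_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class FeatureParams:
    jump_threshold_hz: float = 10_000.0
    modulation_depth_hz: float = 1_000.0
    smoothing_frames: int = 5

    def validate(self) -> None:
        if self.jump_threshold_hz <= 0 or self.modulation_depth_hz <= 0:
            raise ValueError("feature thresholds must be strictly positive")
        if self.smoothing_frames < 1:
            raise ValueError("smoothing_frames must be >= 1")


@dataclass
class TypingParams:
    k_initial: int = 10
    noise_rule: str = "auto"       # "auto" | "manual"
    noise_cluster: int | None = None
    restarts: int = 25
    seed: int = 0

    def validate(self) -> None:
        if self.k_initial < 2:
            raise ValueError("k_initial must be >= 2")
        if self.noise_rule == "manual" and self.noise_cluster is None:
            raise ValueError("manual noise rule requires noise_cluster")


@dataclass
class TransitionParams:
    gap_s: float = 2.0
    edge_threshold: float = 0.05

    def validate(self) -> None:
        if self.gap_s <= 0 or self.edge_threshold < 0:
            raise ValueError("gap_s must be positive and edge_threshold nonnegative")


@dataclass
class StatsParams:
    unit: str = "call"             # "call" | "animal"
    alpha: float = 0.05

    def validate(self) -> None:
        if self.unit not in ("call", "animal"):
            raise ValueError(f"unit must be 'call' or 'animal', got {self.unit!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PipelineConfig:
    stft: StftParams = field(default_factory=StftParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    typing: TypingParams = field(default_factory=TypingParams)
    transitions: TransitionParams = field(default_factory=TransitionParams)
    stats: StatsParams = field(default_factory=StatsParams)

    def validate(self) -> "PipelineConfig":
        for section in (self.stft, self.detection, self.features,
                        self.typing, self.transitions, self.stats):
            section.validate()
        return self

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        sections = {
            "stft": StftParams, "detection": DetectionParams, "features": FeatureParams,
            "typing": TypingParams, "transitions": TransitionParams, "stats": StatsParams,
        }
        unknown = set(d) - set(sections)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        for key, typ in sections.items():
            if key in d:
                kwargs[key] = typ(**d[key])
        return cls(**kwargs).validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))
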