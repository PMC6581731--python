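"""Pipeline configuration: one plain-text file fully determines a run."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    sampling_rate: float = 128.0
    window_s: float = 1.0
    overlap_fraction: float = 0.5
    n_sources: int = 12
    n_channels: int = 32
    sae_layers: list[int] = field(default_factory=lambda: [32, 64, 12])
    lstm_hidden: int = 125
    fc_units: int = 125
    bands: dict[str, list[float]] = field(
        default_factory=lambda: {
            "delta": [0.5, 3.5], "theta": [4.0, 7.0], "alpha": [8.0, 13.0],
            "beta": [14.0, 30.0], "gamma": [31.0, 50.0],
        }
    )
    active_bands: list[str] = field(
        default_factory=lambda: ["theta", "alpha", "beta", "gamma"]
    )
    label_high_threshold: float = 5.5
    label_low_threshold: float = 4.5
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.label_low_threshold > self.label_high_threshold:
            raise ValueError("label_low_threshold must be <= label_high_threshold")
        if len(self.sae_layers) < 2 or self.sae_layers[0] != self.n_channels:
            raise ValueError("sae_layers must start at n_channels")
        if self.sae_layers[-1] != self.n_sources:
            raise ValueError("sae_layers must end at n_sources")

    @property
    def step_s(self) -> float:
        return self.window_s * (1.0 - self.overlap_fraction)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
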