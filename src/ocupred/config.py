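"""Run configuration: one YAML document drives the whole pipeline.

Every pipeline threshold defaults to the paradigm's stated value
(22 deg/s velocity threshold, 16/70 ms peri-saccadic margins, 3 deg
distance rule, 10-valid-trials participant exclusion, 60 Hz filter
cutoff); the stimulus and observer parameters default to the standard
geometry and a plausible observer.  Configs round-trip losslessly through
serialization.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .synthetic_gaze import OculomotorParams

__all__ = ["PipelineThresholds", "RunConfig"]


@dataclass
class PipelineThresholds:
    velocity_threshold: float = 22.0    # deg/s
    filter_cutoff_hz: float = 60.0
    pre_margin: float = 0.016           # s
    post_margin: float = 0.070          # s
    distance_threshold: float = 3.0     # deg
    min_valid_trials: int = 10
    min_saccade_duration: float = 0.010  # s
    merge_gap: float = 0.020             # s


@dataclass
class RunConfig:
    experiment_id: int = 1
    mode: str = "saccade_task"
    n_participants: int = 12
    seed: int = 0
    output_dir: str = "ocupred_out"
    stimulus_overrides: dict = field(default_factory=dict)
    oculomotor: OculomotorParams = field(default_factory=OculomotorParams)
    thresholds: PipelineThresholds = field(default_factory=PipelineThresholds)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "oculomotor" in d and isinstance(d["oculomotor"], dict):
            d["oculomotor"] = OculomotorParams(**d["oculomotor"])
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = PipelineThresholds(**d["thresholds"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
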