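"""Run configuration: every protocol constant in one overridable record.

Defaults reproduce the study protocol — 256 Hz ECG, 128 Hz accelerometer,
2-s movement windows averaged into 1-min vectors, 1-min HRV windows,
13 subjects with two 5-min static and three 10-min dynamic sessions,
p < 0.05 variable selection — and round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .generate import DEFAULT_SCHEDULE, SessionSchedule

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    n_subjects: int = 13
    schedule: list = field(
        default_factory=lambda: [[a.value, m] for a, m in DEFAULT_SCHEDULE.entries]
    )
    ecg_fs: float = 256.0
    accel_fs: float = 128.0
    imu_window_s: float = 2.0
    hrv_window_s: float = 60.0
    ecg_noise_sd: float = 0.05
    scenario: int = 1
    classifier: str = "lsvm"
    k_grid: list = field(default_factory=lambda: [1, 2, 3, 4, 5])
    alpha: float = 0.05
    ee_models: list = field(default_factory=lambda: ["I", "II", "III", "IV"])
    use_true_peaks: bool = False

    def session_schedule(self) -> SessionSchedule:
        return SessionSchedule(entries=tuple((a, m) for a, m in self.schedule))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: "str | Path | None" = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: "str | Path") -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
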