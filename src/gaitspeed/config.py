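"""Pipeline configuration: every tunable of the analysis, with validated defaults.

The config file dialect is flat YAML (``key: value``); unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # -- input units (io_core) ------------------------------------------------
    accel_units: str = "m/s^2"        # or "g"
    gyro_units: str = "rad/s"         # or "deg/s"
    diary_offset_s: float = 0.0       # diary-clock minus sensor-clock offset

    # -- still detection / stride estimation (stride_speed) -------------------
    gyro_thresh: float = 0.8          # rad/s, gyro magnitude below -> candidate still
    accel_band: float = 0.8           # m/s^2, |accel magnitude - g| below -> candidate still
    min_still_s: float = 0.08         # s, minimum still-interval duration
    max_stride_duration_s: float = 4.0
    n_trim_lab: int = 2               # gait cycles removed at each end of a lab trial

    # -- bout segmentation and medication states (bouts_states) ---------------
    max_gap_s: float = 3.0            # max inter-stride gap within a bout
    min_bout_s: float = 15.0          # bouts shorter than this are excluded from summaries
    min_speed_ms: float = 0.2         # stride-speed floor for home summaries
    on_window_min: tuple[float, float] = (60.0, 180.0)
    noton_window_min: tuple[float, float] = (-30.0, 30.0)
    overlap_policy: str = "noton_wins"   # noton_wins | on_wins | drop

    # -- statistics (summaries_stats) -----------------------------------------
    alpha: float = 0.05
    percentile_rule: str = "linear"   # linear interpolation between closest ranks
    transform: str = "log"            # transform for R^2 on non-normal variables
    mt_correction: str = "none"       # none | benjamini_hochberg

    # -- misc ------------------------------------------------------------------
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.accel_units not in ("m/s^2", "g"):
            raise ValueError(f"accel_units must be 'm/s^2' or 'g', got {self.accel_units!r}")
        if self.gyro_units not in ("rad/s", "deg/s"):
            raise ValueError(f"gyro_units must be 'rad/s' or 'deg/s', got {self.gyro_units!r}")
        if self.overlap_policy not in ("noton_wins", "on_wins", "drop"):
            raise ValueError(f"unknown overlap_policy {self.overlap_policy!r}")
        if self.transform not in ("log", "none"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.mt_correction not in ("none", "benjamini_hochberg"):
            raise ValueError(f"unknown mt_correction {self.mt_correction!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("gyro_thresh", "accel_band", "min_still_s", "max_stride_duration_s",
                     "max_gap_s", "min_bout_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - cls.field_names()
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("on_window_min", "noton_window_min"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["on_window_min"] = list(self.on_window_min)
        d["noton_window_min"] = list(self.noton_window_min)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
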