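"""Pipeline configuration with validated defaults and YAML loading."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # zero-phase Butterworth low-pass
    filter_cutoff_hz: float = 10.0
    filter_order: int = 4
    # axis mapping: sensor columns -> (ap, ml, v) before tilt correction
    axes_mapping: tuple = ("x", "y", "z")
    # contact detector
    detector_k_mad: float = 1.5
    detector_min_separation_frac: float = 0.35
    detector_prominence_floor: float = 5.0
    # side labelling
    side_window_s: float = 0.05
    ml_positive_is_right: bool = True
    ml_floor: float = 0.01
    # cycle handling
    trim_events: int = 1
    duration_gate: tuple = (0.6, 2.5)
    n_points: int = 101
    min_cycles: int = 5
    # aggregation / regression / statistics
    aggregation: str = "mean-of-trials"
    regression_scope: str = "per-condition"
    alpha: float = 0.05

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.filter_cutoff_hz <= 0 or self.filter_order < 1:
            raise ConfigError("filter settings out of range")
        if sorted(self.axes_mapping) != ["x", "y", "z"]:
            raise ConfigError("axes_mapping must be a permutation of x, y, z")
        if not (0 < self.detector_min_separation_frac < 1):
            raise ConfigError("detector_min_separation_frac must be in (0, 1)")
        if self.detector_k_mad < 0 or self.detector_prominence_floor < 1:
            raise ConfigError("detector thresholds out of range")
        if self.n_points < 4 or self.min_cycles < 1 or self.trim_events < 0:
            raise ConfigError("cycle settings out of range")
        lo, hi = self.duration_gate
        if not (0 < lo < hi):
            raise ConfigError("duration_gate must satisfy 0 < lo < hi")
        if self.aggregation not in ("mean-of-trials", "pool-cycles"):
            raise ConfigError(f"unknown aggregation {self.aggregation!r}")
        if self.regression_scope not in ("per-condition", "pooled"):
            raise ConfigError(f"unknown regression scope {self.regression_scope!r}")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["axes_mapping"] = list(self.axes_mapping)
        d["duration_gate"] = list(self.duration_gate)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("axes_mapping", "duration_gate"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)
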