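"""Run configuration: schema-validated YAML/JSON with unknown keys rejected."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import yaml

from .detection import DetectionConfig
from .scoring import BehaviorWeights, ScoreConfig
from .synthetic import BREED_RATE_SPECS, BehaviorRateSpec

__all__ = ["RunConfig", "load_config"]


def _build(cls, d: Mapping, ctx: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown keys in {ctx}: {sorted(unknown)}")
    return cls(**d)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; fully serializable."""

    seed: int = 0
    duration_h: float = 1.0
    sample_rate_hz: float = 50.0
    noise_sd: float = 0.05
    breed: str = "other"
    rates: BehaviorRateSpec = None
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    weights: BehaviorWeights = field(default_factory=BehaviorWeights)
    risk_penalty: float = 0.5
    thresholds_override: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.rates is None:
            spec = BREED_RATE_SPECS.get(self.breed, BehaviorRateSpec(breed=self.breed))
            object.__setattr__(self, "rates", spec)

    @property
    def score_config(self) -> ScoreConfig:
        return ScoreConfig(risk_penalty=self.risk_penalty)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "duration_h": self.duration_h,
            "sample_rate_hz": self.sample_rate_hz,
            "noise_sd": self.noise_sd,
            "breed": self.breed,
            "rates": {
                "breed": self.rates.breed,
                "scratch_per_hour": self.rates.scratch_per_hour,
                "lick_per_hour": self.rates.lick_per_hour,
                "swallow_per_hour": self.rates.swallow_per_hour,
                "sleep_hours_per_day": self.rates.sleep_hours_per_day,
            },
            "detection": dataclasses.asdict(self.detection),
            "weights": {
                "scratch": self.weights.scratch, "lick": self.weights.lick,
                "swallow": self.weights.swallow, "sleep": self.weights.sleep,
            },
            "risk_penalty": self.risk_penalty,
            "thresholds_override": self.thresholds_override,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        rates = d.pop("rates", None)
        detection = d.pop("detection", None)
        weights = d.pop("weights", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown keys in run config: {sorted(unknown)}")
        kwargs = dict(d)
        if rates is not None:
            kwargs["rates"] = BehaviorRateSpec.from_dict(rates)
        if detection is not None:
            det = {k: tuple(v) if isinstance(v, list) else v for k, v in detection.items()}
            kwargs["detection"] = _build(DetectionConfig, det, "detection config")
        if weights is not None:
            kwargs["weights"] = _build(BehaviorWeights, weights, "weights")
        return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    with open(path) as fh:
        text = fh.read()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ValueError("run config must be a mapping")
    return RunConfig.from_dict(data)
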