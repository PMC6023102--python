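"""Structured run configuration (YAML).

A config file groups the metric options and the simulation protocol in one
place; every numeric field is validated by the constructor of the module it
belongs to, so a bad value fails at load time with a clear message.

Example::

    metrics:
      bandwidth: 10.0
      gamma: 0.95
      reference_distribution: {mu: 4.9165, sigma: 0.3832, upper: 450.0}
      bins: {low: 40.0, high: 420.0, width: 20.0}
    simulation:
      protocol: {n_subjects: 12, n_days: 7}
      sensor: {tau: 11.0, noise_sd_percent: 5.0}
      err_ref_percent: 5.0
      reps: 1000
      seed: 1
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .exceptions import InvalidInputError
from .metrics import RangeBinning
from .reference_error import ReferenceErrorModel
from .synthetic import ProtocolConfig, SensorConfig
from .wmard import ReferenceDistribution


@dataclass(frozen=True)
class MetricOptions:
    bins: RangeBinning = field(default_factory=RangeBinning)
    bandwidth: float = 10.0
    reference_distribution: ReferenceDistribution = field(
        default_factory=ReferenceDistribution
    )
    gamma: float = 0.95

    def __post_init__(self):
        if not (0.0 < self.gamma < 1.0):
            raise InvalidInputError("gamma must be in (0, 1)")
        if self.bandwidth <= 0:
            raise InvalidInputError("bandwidth must be > 0")


@dataclass(frozen=True)
class SimulationOptions:
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    sensor: SensorConfig = field(default_factory=SensorConfig)
    err_ref_percent: float = 5.0
    reps: int = 1000
    seed: Optional[int] = None

    def __post_init__(self):
        if self.err_ref_percent < 0:
            raise InvalidInputError("err_ref_percent must be >= 0")
        if self.reps < 1:
            raise InvalidInputError("reps must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    metrics: MetricOptions = field(default_factory=MetricOptions)
    simulation: SimulationOptions = field(default_factory=SimulationOptions)


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise InvalidInputError(f"{path}: top level must be a mapping")

    def build(cls, data, **nested):
        data = dict(data or {})
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise InvalidInputError(f"{path}: unknown keys {sorted(unknown)} for {cls.__name__}")
        for key, sub_cls in nested.items():
            if key in data:
                data[key] = build(sub_cls, data[key])
        try:
            return cls(**data)
        except TypeError as exc:
            raise InvalidInputError(f"{path}: {exc}") from exc

    metrics = build(
        MetricOptions,
        raw.get("metrics"),
        bins=RangeBinning,
        reference_distribution=ReferenceDistribution,
    )
    sim_raw = dict(raw.get("simulation") or {})
    if isinstance(sim_raw.get("sensor"), dict) and "calibration_error" in sim_raw["sensor"]:
        sim_raw["sensor"] = dict(sim_raw["sensor"])
        sim_raw["sensor"]["calibration_error"] = build(
            ReferenceErrorModel, sim_raw["sensor"]["calibration_error"]
        )
    if isinstance(sim_raw.get("protocol"), dict) and "excursion_days" in sim_raw["protocol"]:
        sim_raw["protocol"] = dict(sim_raw["protocol"])
        sim_raw["protocol"]["excursion_days"] = tuple(sim_raw["protocol"]["excursion_days"])
    simulation = build(
        SimulationOptions,
        sim_raw,
        protocol=ProtocolConfig,
        sensor=SensorConfig,
    )
    return RunConfig(metrics=metrics, simulation=simulation)
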