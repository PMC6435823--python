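"""Run configuration: nested dataclasses loaded from YAML, unknown keys rejected."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

__all__ = [
    "SimulateConfig",
    "PunctaConfig",
    "EventsConfig",
    "PairedConfig",
    "RunConfig",
    "load_config",
    "dump_config",
]


def _from_dict(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class SimulateConfig:
    n_az: int = 100
    field: tuple = (256, 256)
    n_stimuli: int = 100
    psf_sigma: float = 1.5
    background: float = 20.0
    noise_sd: float = 3.0
    jitter_sd: float = 1.0
    min_spacing: float = 8.0
    level_shape: float = 2.0
    level_scale: float = 300.0
    level_loc: float = 250.0
    coupling_slope: float = 0.5
    coupling_noise_sd: float = 0.03
    second_channel_r: float = 0.95
    perturbation_mode: str = "multiplicative"
    perturbation_param: float = 1.5
    perturbation_noise_cv: float = 0.1
    vehicle_drift: float = 1.0
    n_vehicle_az: int = 100


@dataclass
class PunctaConfig:
    gaussian_sigma: float = 0.75
    noise_tolerance: float | None = None
    min_intensity: float | None = None
    background_method: str = "constant"
    background_radius: int = 15


@dataclass
class EventsConfig:
    max_radius: float | None = None


@dataclass
class PairedConfig:
    rel_tol: float = 0.05
    use_corrected: bool = True


@dataclass
class RunConfig:
    """Top-level run configuration; every stage's parameters plus the seed."""

    seed: int = 0
    stages: tuple = ("simulate", "puncta", "release", "paired")
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    puncta: PunctaConfig = field(default_factory=PunctaConfig)
    events: EventsConfig = field(default_factory=EventsConfig)
    paired: PairedConfig = field(default_factory=PairedConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for name, sub in (
            ("simulate", SimulateConfig),
            ("puncta", PunctaConfig),
            ("events", EventsConfig),
            ("paired", PairedConfig),
        ):
            if name in data and isinstance(data[name], dict):
                data[name] = _from_dict(sub, data[name])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "simulate" in data and isinstance(data["simulate"], SimulateConfig):
            data["simulate"].field = tuple(data["simulate"].field)
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["simulate"]["field"] = list(self.simulate.field)
        return d


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
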