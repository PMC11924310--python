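"""Pipeline configuration: defaults per stage, strict key checking, YAML round trip."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .errors import ConfigurationError


def _strict_from_mapping(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) for {cls.__name__}: {sorted(unknown)}"
        )
    return cls(**data)


@dataclasses.dataclass
class TPCStageConfig:
    temperatures: list[float] = dataclasses.field(
        default_factory=lambda: [-0.5, 2.3, 5.0, 7.3, 9.9, 12.3, 15.0]
    )
    replicates: int = 4
    noise_sd: float = 0.03
    n_boot: int = 1000
    truth: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"a": 0.45, "b": 0.05, "z": 7.0, "w": 26.0}
    )


@dataclasses.dataclass
class PhotoperiodStageConfig:
    photoperiods: list[float] = dataclasses.field(
        default_factory=lambda: [1.0, 4.0, 8.0, 16.0, 24.0]
    )
    n_strains: int = 4
    replicates: int = 6
    noise_cv: float = 0.05
    basis_dim: int = 5


@dataclasses.dataclass
class UptakeStageConfig:
    substrate_levels: list[float] = dataclasses.field(
        default_factory=lambda: [0.1, 0.4, 0.8, 2.0, 10.0, 50.0, 100.0]
    )
    replicates: int = 4
    noise_cv: float = 0.02
    v_max: float = 2e-7
    k_s: float = 1.5
    n_boot: int = 500


@dataclasses.dataclass
class CaasStageConfig:
    n_clusters: int = 10
    length: int = 300
    n_planted: int = 5
    substitution_prob: float = 0.02
    window: int = 5
    max_other_variability: float = 0.3
    use_independence: bool = True
    clusters_dir: str | None = None  # read real clusters instead of simulating
    tree: str | None = None
    annotations: str | None = None


@dataclasses.dataclass
class PipelineConfig:
    stages: list[str] = dataclasses.field(
        default_factory=lambda: ["tpc", "photoperiod", "uptake", "caas"]
    )
    seed: int = 0
    out_dir: str = "polartrait_out"
    tpc: TPCStageConfig = dataclasses.field(default_factory=TPCStageConfig)
    photoperiod: PhotoperiodStageConfig = dataclasses.field(
        default_factory=PhotoperiodStageConfig
    )
    uptake: UptakeStageConfig = dataclasses.field(default_factory=UptakeStageConfig)
    caas: CaasStageConfig = dataclasses.field(default_factory=CaasStageConfig)

    _STAGE_CLASSES = {
        "tpc": TPCStageConfig,
        "photoperiod": PhotoperiodStageConfig,
        "uptake": UptakeStageConfig,
        "caas": CaasStageConfig,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        for name, sub_cls in cls._STAGE_CLASSES.items():
            if name in data:
                kwargs[name] = _strict_from_mapping(sub_cls, data.pop(name) or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown top-level key(s): {sorted(unknown)}")
        bad_stages = set(data.get("stages", [])) - set(cls._STAGE_CLASSES)
        if bad_stages:
            raise ConfigurationError(f"unknown stage(s): {sorted(bad_stages)}")
        return cls(**kwargs, **data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
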