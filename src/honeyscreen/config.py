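"""Pipeline configuration: every screening/chemometrics threshold in one place.

The config is a flat, versioned key-value schema loadable from YAML.
Unknown keys are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

__all__ = ["PipelineConfig", "ConfigError"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    schema_version: int = SCHEMA_VERSION
    # screening
    mass_tol_target_mda: float = 5.0
    mass_tol_annotation_mda: float = 2.0
    msigma_max: float = 50.0
    min_intensity: float = 1000.0
    min_area: float = 2000.0
    rt_tol_target_min: float = 0.2
    rt_window_suspect_min: float = 1.8
    similarity_min: float = 0.7
    min_matched_fragments: int = 3
    # non-target filtering
    blank_fold: float = 5.0
    qc_rsd_max: float = 30.0
    # chemometrics
    scaling: str = "vast"
    n_components: int = 2
    vip_cutoff: float = 1.0
    n_test: int = 11
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported schema_version {self.schema_version}")
        positive = (
            "mass_tol_target_mda",
            "mass_tol_annotation_mda",
            "msigma_max",
            "rt_tol_target_min",
            "rt_window_suspect_min",
            "blank_fold",
            "qc_rsd_max",
            "vip_cutoff",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.similarity_min <= 1:
            raise ConfigError("similarity_min must be in (0, 1]")
        if self.scaling not in ("autoscale", "pareto", "vast"):
            raise ConfigError(f"unknown scaling {self.scaling!r}")
        if self.n_components < 1:
            raise ConfigError("n_components must be >= 1")
        if self.n_test < 1:
            raise ConfigError("n_test must be >= 1")
        if self.min_matched_fragments < 1:
            raise ConfigError("min_matched_fragments must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
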