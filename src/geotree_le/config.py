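"""Pipeline configuration: a validated, round-trippable YAML document."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # inputs; None + synthetic=True means "generate them"
    synthetic: bool = True
    elevation_path: str | None = None
    population_path: str | None = None
    zones_path: str | None = None
    panel_path: str | None = None
    scenario_path: str | None = None

    # synthetic-world knobs
    seed: int = 20301231
    n_regions: int = 31
    years: list = field(default_factory=lambda: [2000, 2010, 2020])
    grid_shape: list = field(default_factory=lambda: [64, 64])
    type_mix: list = field(default_factory=lambda: [0.70, 0.23, 0.07])

    # thresholds
    env_thresholds: list = field(default_factory=lambda: [300.0, 950.0])
    stage_thresholds: list = field(default_factory=lambda: [30.0, 70.0])
    stratify_mode: str = "fixed"  # or "jenks"

    # model options
    covariates: list | None = None  # None -> stepwise selection decides
    select: bool = False
    cv_folds: int | None = None    # None -> leave-one-region-out
    interval_level: float = 0.95
    target_year: int = 2030

    out_dir: str = "results"

    def validate(self) -> "PipelineConfig":
        if not self.synthetic:
            needed = {
                "elevation_path": self.elevation_path,
                "population_path": self.population_path,
                "zones_path": self.zones_path,
                "panel_path": self.panel_path,
            }
            missing = [k for k, v in needed.items() if v is None]
            if missing:
                raise ConfigError(
                    f"non-synthetic mode requires input paths: {missing}"
                )
        if not 0.0 <= self.interval_level < 1.0:
            raise ConfigError("interval_level must be in [0, 1)")
        if len(self.env_thresholds) != 2 or len(self.stage_thresholds) != 2:
            raise ConfigError("thresholds must be (lower, upper) pairs")
        if self.stratify_mode not in {"fixed", "jenks"}:
            raise ConfigError(f"unknown stratify_mode {self.stratify_mode!r}")
        if self.target_year <= max(self.years):
            raise ConfigError("target_year must follow the last panel year")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc).validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)
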