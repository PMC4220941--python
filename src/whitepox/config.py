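"""Pipeline configuration: YAML-backed, defaulted, unknown keys rejected."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .covariates import DesignOptions
from .field import Hyperparameters

__all__ = ["ConfigError", "PipelineConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (the message names the offending key)."""


@dataclass
class DataBlock:
    panel: str | None = None
    column_map: dict = field(default_factory=dict)


@dataclass
class CovariatesBlock:
    standardize: bool = True
    log10_size: bool = True
    log10_distances: bool = True
    episode_counting: bool = False
    prev_infected_fill: str = "max_pairwise"

    def to_options(self) -> DesignOptions:
        return DesignOptions(**asdict(self))


@dataclass
class ModelBlock:
    nu: float = 1.0
    beta_prior_sd: float = 10.0
    grid_points: int = 5
    grid_span: float = 2.0
    strategy: str = "auto"
    empirical_bayes: bool = False
    hyper_fixed: dict = field(default_factory=dict)

    def fixed_hyper(self) -> Hyperparameters | None:
        if not self.empirical_bayes and not self.hyper_fixed:
            return None
        return Hyperparameters(nu=self.nu, **self.hyper_fixed)


@dataclass
class IntensityBlock:
    bandwidth: float | None = None
    grid: int = 128
    annualize: bool = False


@dataclass
class RunBlock:
    seed: int = 0
    output_dir: str = "whitepox_out"
    log_level: str = "INFO"


@dataclass
class PipelineConfig:
    data: DataBlock = field(default_factory=DataBlock)
    covariates: CovariatesBlock = field(default_factory=CovariatesBlock)
    model: ModelBlock = field(default_factory=ModelBlock)
    intensity: IntensityBlock = field(default_factory=IntensityBlock)
    run: RunBlock = field(default_factory=RunBlock)


_BLOCKS = {
    "data": DataBlock,
    "covariates": CovariatesBlock,
    "model": ModelBlock,
    "intensity": IntensityBlock,
    "run": RunBlock,
}


def _build_block(cls, payload: dict, block_name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown key '{sorted(unknown)[0]}' in block '{block_name}'")
    return cls(**payload)


def load_config(path_or_dict) -> PipelineConfig:
    """Load a pipeline config from a YAML file path or an in-memory mapping."""
    if isinstance(path_or_dict, dict):
        payload = path_or_dict
    else:
        with open(path_or_dict) as fh:
            payload = yaml.safe_load(fh) or {}
    if not isinstance(payload, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(payload) - set(_BLOCKS)
    if unknown:
        raise ConfigError(f"unknown top-level key '{sorted(unknown)[0]}'")
    kwargs = {}
    for name, cls in _BLOCKS.items():
        block = payload.get(name, {})
        if not isinstance(block, dict):
            raise ConfigError(f"block '{name}' must be a mapping")
        kwargs[name] = _build_block(cls, block, name)
    return PipelineConfig(**kwargs)
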