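"""YAML run configuration: model parameters plus per-command settings.

A config file is a mapping with a mandatory ``params`` block (either a
``preset`` name or the explicit ModelParams fields, with explicit fields
overriding the preset) and optional ``integration``, ``grid``, ``sweep``,
``output`` blocks.  Every field has a default, so the minimal valid config
is just a preset name; configs round-trip losslessly through
:func:`save_config` / :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .basins import DEFAULT_GRID, MARGIN
from .dynamics import DIST_TOL, RTOL, ATOL, T_END
from .model import DomainError, ModelParams
from .presets import get_preset

__all__ = ["ConfigError", "RunConfig", "load_config", "save_config"]

_PARAM_FIELDS = [f.name for f in dataclasses.fields(ModelParams)]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class IntegrationConfig:
    t_end: float = T_END
    rtol: float = RTOL
    atol: float = ATOL
    method: str = "RK45"
    dist_tol: float = DIST_TOL
    x0: float | None = None
    r0: float | None = None
    c0: float | None = None


@dataclass
class GridConfig:
    nx: int = DEFAULT_GRID[0]
    nr: int = DEFAULT_GRID[1]
    nc: int = DEFAULT_GRID[2]
    margin: float = MARGIN
    jitter: float = 0.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.nr, self.nc)


@dataclass
class SweepConfig:
    m_values: list[int] = field(default_factory=list)
    level: str = "alpha"


@dataclass
class RunConfig:
    params: ModelParams
    preset: str | None = None
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    outdir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = {
            "params": dataclasses.asdict(self.params),
            "integration": dataclasses.asdict(self.integration),
            "grid": dataclasses.asdict(self.grid),
            "sweep": dataclasses.asdict(self.sweep),
            "outdir": self.outdir,
            "seed": self.seed,
            "log_level": self.log_level,
        }
        if self.preset:
            d["preset"] = self.preset
        return d


def _build_params(raw: dict) -> tuple[ModelParams, str | None]:
    preset = raw.get("preset")
    block = dict(raw.get("params") or {})
    unknown = set(block) - set(_PARAM_FIELDS)
    if unknown:
        raise ConfigError(f"unknown params field(s): {', '.join(sorted(unknown))}")
    if preset is not None:
        base = dataclasses.asdict(get_preset(preset))
        base.update(block)
        block = base
    missing = [f for f in _PARAM_FIELDS if f not in block and f not in ("eps1", "eps2")]
    if missing:
        raise ConfigError(f"missing params field(s): {', '.join(missing)}")
    try:
        return ModelParams(**block), preset
    except DomainError as exc:
        raise ConfigError(str(exc)) from exc


def _build_block(cls, raw: dict | None, name: str):
    raw = dict(raw or {})
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown {name} field(s): {', '.join(sorted(unknown))}")
    return cls(**raw)


def config_from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    params, preset = _build_params(raw)
    cfg = RunConfig(
        params=params,
        preset=preset,
        integration=_build_block(IntegrationConfig, raw.get("integration"), "integration"),
        grid=_build_block(GridConfig, raw.get("grid"), "grid"),
        sweep=_build_block(SweepConfig, raw.get("sweep"), "sweep"),
        outdir=str(raw.get("outdir", ".")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
    for n in (cfg.grid.nx, cfg.grid.nr, cfg.grid.nc):
        if n < 2:
            raise ConfigError(f"grid resolutions must be >= 2, got {cfg.grid.shape}")
    if cfg.sweep.level not in ("alpha", "beta"):
        raise ConfigError(f"sweep.level must be 'alpha' or 'beta', got {cfg.sweep.level!r}")
    return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
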