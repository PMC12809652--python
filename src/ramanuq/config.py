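"""Run configuration: one YAML file drives the whole pipeline.

Every study constant (alpha = 0.1, z ~ 1.64, Savitzky-Golay window 11 /
order 2, grid 350-2000 cm^-1 at 1 cm^-1, calibration size 100, 10 folds)
appears as a named default on the corresponding sub-config, never as a
buried literal. A single global seed deterministically derives per-stage
seeds.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .conformal import DEFAULT_ALPHA
from .evaluate import CVPlan
from .nn import BackboneConfig
from .preprocess import PreprocessConfig
from .synthetic import SyntheticConfig
from .uq import METHODS, TrainingConfig

__all__ = ["ConformalSettings", "RunConfig", "ConfigError", "validate_config", "stage_seed"]


class ConfigError(ValueError):
    """All config problems collected into one error, with field paths."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems))


class ConformalSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha: float = DEFAULT_ALPHA
    z: float | None = None  # None -> standard-normal quantile for 1 - alpha/2

    @model_validator(mode="after")
    def _check(self) -> "ConformalSettings":
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.z is not None and self.z <= 0:
            raise ValueError("z must be positive")
        return self


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    output_dir: str = "runs/default"
    log_level: str = "INFO"
    methods: list[str] = ["het_gaussian"]
    test_fraction: float = 0.2
    no_conformal: bool = False  # evaluate raw sigma-hat intervals (ablation mode)
    levels: list[float] | None = None  # coverage-curve levels; None -> default ladder
    synthetic: SyntheticConfig = SyntheticConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    backbone: BackboneConfig = BackboneConfig()
    training: TrainingConfig = TrainingConfig()
    conformal: ConformalSettings = ConformalSettings()
    cv: CVPlan = CVPlan()

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; choose from {list(METHODS)}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.levels is not None and any(not 0.0 < L < 1.0 for L in self.levels):
            raise ValueError("levels must lie in (0, 1)")
        return self


def _format_pydantic_errors(err: ValidationError) -> list[str]:
    out = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        out.append(f"{loc}: {e['msg']}")
    return out


def validate_config(path: str | Path) -> RunConfig:
    """Parse, default and cross-validate a YAML run config.

    All violations (unknown keys, range errors) are collected and reported
    together, each with its field path.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError([f"not valid YAML: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError(["top level of the config must be a mapping"])
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(_format_pydantic_errors(exc)) from exc


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2^31) derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))
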