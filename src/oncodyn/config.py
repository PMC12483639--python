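"""Validated run configuration (YAML/JSON).

A RunConfig is a set of optional blocks mirroring the library's parameter
objects.  Validation is strict: unknown keys are rejected and errors name the
offending key path.  Units are normalized at load time (ages and the life
expectancy are given in years; the mutation process stores days internally).
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .growth import GrowthParams
from .immune import ImmuneParams, LifeHistoryConfig
from .mutation import MutationParams

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration file failed validation; the message names the key."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GrowthBlock(_Block):
    model: str = Field(pattern="^(richards|erm1|erm2)$")
    nu: float = Field(gt=0)
    r: float = Field(gt=0)
    mu: float | None = Field(default=None, ge=0)
    gamma: float | None = Field(default=None, ge=0)
    s: float | None = Field(default=None, ge=0)
    # alternative threshold/capacity parameterization
    A: float | None = Field(default=None, gt=0)
    K: float | None = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check(self):
        if (self.A is None) != (self.K is None):
            raise ValueError("A and K must be given together")
        if self.A is None and self.mu is None:
            raise ValueError("either mu or the (A, K) pair is required")
        return self

    def to_params(self) -> GrowthParams:
        if self.A is not None:
            if self.model == "erm1":
                return GrowthParams.erm1_from_thresholds(self.nu, self.r, self.A, self.K)
            if self.model == "erm2":
                return GrowthParams.erm2_from_thresholds(self.nu, self.r, self.A, self.K)
            return GrowthParams.richards_from_capacity(self.nu, self.r, self.K)
        return GrowthParams(self.model, nu=self.nu, r=self.r, mu=self.mu,
                            gamma=self.gamma, s=self.s)


class MutationBlock(_Block):
    n: int = Field(ge=1)
    p0: float = Field(gt=0, lt=1)
    delta_percent: float = Field(default=0.0, ge=0)
    life_expectancy_years: float = Field(default=84.0, gt=0)

    def to_params(self) -> MutationParams:
        return MutationParams.from_years(
            n=self.n,
            p0=self.p0,
            delta=self.delta_percent,
            life_expectancy_years=self.life_expectancy_years,
        )


class ImmuneBlock(_Block):
    case: int = Field(default=3, ge=0, le=3)
    s_min: float = Field(ge=0)
    s_max: float = Field(ge=0)
    menarche_age: float = 12.0
    luteal_days: float = 14.0
    follicular_mean: float = 14.0
    follicular_sd: float = 2.4
    fixed_follicular_days: float | None = None
    menopause_mean: float = 51.0
    menopause_sd: float = 4.86
    hrt_fraction: float = Field(default=0.26, ge=0, le=1)
    hrt_mode: float = 6.0
    hrt_sd: float = 4.8

    def to_params(self) -> tuple[ImmuneParams, LifeHistoryConfig]:
        immune = ImmuneParams(
            s_min=self.s_min,
            s_max=self.s_max,
            hrt_fraction=self.hrt_fraction,
            hrt_mode=self.hrt_mode,
            hrt_sd=self.hrt_sd,
        )
        life = LifeHistoryConfig(
            case=self.case,
            menarche_age=self.menarche_age,
            luteal_days=self.luteal_days,
            follicular_mean=self.follicular_mean,
            follicular_sd=self.follicular_sd,
            fixed_follicular_days=self.fixed_follicular_days,
            menopause_mean=self.menopause_mean,
            menopause_sd=self.menopause_sd,
            hrt_fraction=self.hrt_fraction,
            hrt_mode=self.hrt_mode,
            hrt_sd=self.hrt_sd,
        )
        return immune, life


class RiskBlock(_Block):
    n_women: int = Field(default=2000, ge=100)
    horizon_years: float = Field(default=85.0, gt=0, le=110)
    age_cut: float = 51.0


class FitBlock(_Block):
    model: str = Field(default="erm2", pattern="^(richards|erm1|erm2)$")
    free: list[str] | None = None
    log_scale: bool = True


class RunConfig(_Block):
    growth: GrowthBlock | None = None
    mutation: MutationBlock | None = None
    immune: ImmuneBlock | None = None
    risk: RiskBlock = RiskBlock()
    fit: FitBlock = FitBlock()
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def resolved_dict(self) -> dict:
        return json.loads(self.model_dump_json())


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON config file.

    Defaults are filled for optional keys; schema violations raise a
    ConfigError whose message names the offending key and constraint.
    """
    text = Path(path).read_text()
    if str(path).endswith((".json",)):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigError(f"config key '{loc}': {first['msg']}") from exc
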