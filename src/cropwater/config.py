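"""Run configuration: a structured description of one crop season.

A run names the site, the soil (composition for the pedotransfer step, or
measured hydraulic limits directly), the crop and any parameter overrides,
the growing period (explicit ISO dates or the early/mid/late month classes
standing for the 5th/15th/25th), the initial soil-moisture class, the
irrigation plan, the harvested yield, and the weather source (a CSV file or
a seeded synthetic climate).  Configurations round-trip through YAML.
"""

from __future__ import annotations

import datetime
from typing import Optional, Union

import yaml
from pydantic import BaseModel, model_validator

from .crop import CropParameters, get_crop
from .meteorology import SiteInfo
from .soil import SoilComposition, SoilHydraulics, pedotransfer
from .synthetic_weather import ClimateRegime, ClimateSpec, climate_preset
from .water_balance import (
    BalanceOptions,
    IrrigationMethod,
    IrrigationPlan,
    MoistureClass,
    TimingClass,
    resolve_date_class,
)


class DateClassSpec(BaseModel):
    """A month plus an early/mid/late timing class."""

    year: int
    month: int
    timing: TimingClass


DateLike = Union[datetime.date, str, DateClassSpec, dict]


def resolve_date(value: DateLike) -> datetime.date:
    """Resolve an explicit date, an ISO string, or a month timing class."""
    if isinstance(value, datetime.date):
        return value
    if isinstance(value, str):
        return datetime.date.fromisoformat(value)
    if isinstance(value, dict):
        value = DateClassSpec(**value)
    return resolve_date_class(value.month, value.year, value.timing)


class SoilSpec(BaseModel):
    """Either a composition (pedotransfer input) or direct hydraulic limits;
    local measurements take precedence when both are given."""

    composition: Optional[SoilComposition] = None
    hydraulics: Optional[SoilHydraulics] = None
    density_factor: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "SoilSpec":
        if self.composition is None and self.hydraulics is None:
            raise ValueError("soil needs either a composition or hydraulics")
        return self

    def resolve(self) -> SoilHydraulics:
        if self.hydraulics is not None:
            return self.hydraulics
        return pedotransfer(self.composition, density_factor=self.density_factor)


class CropSpec(BaseModel):
    name: str
    overrides: dict = {}
    table_path: Optional[str] = None

    def resolve(self) -> CropParameters:
        return get_crop(self.name, overrides=self.overrides, path=self.table_path)


class IrrigationSpec(BaseModel):
    method: IrrigationMethod
    total_depth: float = 0.0
    n_events: int = 1
    start: Optional[DateLike] = None
    end: Optional[DateLike] = None

    def resolve(self) -> IrrigationPlan:
        return IrrigationPlan(
            method=self.method,
            total_depth=self.total_depth,
            n_events=self.n_events,
            start_date=resolve_date(self.start) if self.start is not None else None,
            end_date=resolve_date(self.end) if self.end is not None else None,
        )


class WeatherSource(BaseModel):
    """Where the daily weather comes from: a CSV path, a full climate
    specification, or a named regime preset."""

    csv: Optional[str] = None
    climate: Optional[ClimateSpec] = None
    regime: Optional[ClimateRegime] = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "WeatherSource":
        if self.csv is None and self.climate is None and self.regime is None:
            raise ValueError("weather needs a csv path, a climate spec, or a regime preset")
        return self

    def resolve_climate(self) -> Optional[ClimateSpec]:
        if self.climate is not None:
            return self.climate
        if self.regime is not None:
            return climate_preset(self.regime, seed=self.seed)
        return None


class RunOptions(BaseModel):
    """Model switches: runoff exponent, daily depletion-fraction adjustment,
    whether Pnet in the irrigation requirement also nets out irrigation,
    and the radiation-from-temperature coefficient."""

    runoff_beta: float = 1.0
    adjust_depletion: bool = True
    literal_pnet: bool = False
    k_rs: float = 0.16

    def balance_options(self) -> BalanceOptions:
        return BalanceOptions(runoff_beta=self.runoff_beta,
                              adjust_depletion=self.adjust_depletion)


class RunConfig(BaseModel):
    """Everything needed to simulate one crop season."""

    name: str = "run"
    site: SiteInfo
    soil: SoilSpec
    crop: CropSpec
    sowing: DateLike
    harvest: DateLike
    initial_moisture: MoistureClass = MoistureClass.MID
    irrigation: Optional[IrrigationSpec] = None
    yield_kg_ha: float
    weather: WeatherSource
    options: RunOptions = RunOptions()

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.yield_kg_ha <= 0:
            raise ValueError("yield_kg_ha must be positive")
        if resolve_date(self.harvest) <= resolve_date(self.sowing):
            raise ValueError("harvest must fall after sowing")
        return self


def load_config(path) -> RunConfig:
    """Load a run configuration from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig(**data)


def dump_config(config: RunConfig, path) -> None:
    """Write a run configuration to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
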