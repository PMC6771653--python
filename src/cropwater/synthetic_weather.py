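"""Seeded synthetic daily weather for testing and demonstration.

The generator produces internally consistent daily series: a sinusoidal
annual temperature cycle with autocorrelated noise, precipitation from a
two-state (wet/dry) occurrence chain with exponentially distributed wet-day
depths, solar radiation as a clear-sky fraction reduced on wet days, and
relative humidity anti-correlated with the temperature anomaly and raised
on wet days.  Three climate presets (arid, temperate, humid) cover the
regimes the balance needs to be exercised in.  Everything is reproducible
from the seed recorded in the specification.
"""

from __future__ import annotations

import datetime
import math
from enum import Enum
from typing import Optional

import numpy as np
from pydantic import BaseModel, model_validator

from .meteorology import (
    DailyWeather,
    clear_sky_radiation,
    extraterrestrial_radiation,
)


class ClimateRegime(str, Enum):
    ARID = "arid"
    TEMPERATE = "temperate"
    HUMID = "humid"


class ClimateSpec(BaseModel):
    """Statistical description of a site's climate.

    ``wet_day_prob`` is the stationary frequency of wet days;
    ``wet_persistence`` the excess probability of a wet day following a wet
    day (chain autocorrelation).  Temperatures in degC, depths in mm.
    """

    regime: ClimateRegime = ClimateRegime.TEMPERATE
    t_annual_mean: float = 12.0
    t_annual_amplitude: float = 9.0
    t_daily_range: float = 10.0
    wet_day_prob: float = 0.3
    wet_persistence: float = 0.3
    wet_day_mean_depth: float = 5.0
    rh_baseline: float = 65.0
    latitude: float = 45.0
    elevation: float = 0.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ClimateSpec":
        for name in ("wet_day_prob", "wet_persistence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.wet_day_mean_depth < 0:
            raise ValueError("wet_day_mean_depth must be >= 0")
        if not (0.0 <= self.rh_baseline <= 100.0):
            raise ValueError("rh_baseline outside [0, 100]")
        if abs(self.latitude) > 90:
            raise ValueError("latitude outside [-90, 90]")
        return self


#: Climate presets.  The arid preset mirrors a continental steppe/desert
#: margin (hot summers, rare convective rain), the temperate preset a
#: mid-latitude agricultural climate, and the humid preset a wet tropical
#: lowland.
PRESETS: dict[ClimateRegime, dict] = {
    ClimateRegime.ARID: dict(
        regime=ClimateRegime.ARID, t_annual_mean=20.0, t_annual_amplitude=10.0,
        t_daily_range=14.0, wet_day_prob=0.06, wet_persistence=0.2,
        wet_day_mean_depth=6.0, rh_baseline=35.0, latitude=32.0,
    ),
    ClimateRegime.TEMPERATE: dict(
        regime=ClimateRegime.TEMPERATE, t_annual_mean=11.0, t_annual_amplitude=9.0,
        t_daily_range=9.0, wet_day_prob=0.35, wet_persistence=0.3,
        wet_day_mean_depth=5.0, rh_baseline=70.0, latitude=50.0,
    ),
    ClimateRegime.HUMID: dict(
        regime=ClimateRegime.HUMID, t_annual_mean=25.0, t_annual_amplitude=3.0,
        t_daily_range=8.0, wet_day_prob=0.45, wet_persistence=0.35,
        wet_day_mean_depth=10.0, rh_baseline=80.0, latitude=10.0,
    ),
}


def climate_preset(regime: ClimateRegime | str, seed: int = 0, **overrides) -> ClimateSpec:
    """A preset ClimateSpec for the named regime, with optional overrides."""
    kwargs = dict(PRESETS[ClimateRegime(regime)])
    kwargs.update(overrides)
    kwargs["seed"] = seed
    return ClimateSpec(**kwargs)


def generate_weather(
    spec: ClimateSpec,
    start_date: datetime.date,
    n_days: int,
    seed: Optional[int] = None,
) -> list[DailyWeather]:
    """Generate ``n_days`` of daily weather from ``start_date``.

    One seeded generator drives all variables, so the same spec and seed
    always reproduce the same series bit for bit.  ``seed`` overrides the
    spec's seed when given.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    # two-state precipitation occurrence chain with stationary frequency
    # wet_day_prob and lag-1 excess persistence wet_persistence
    pi = spec.wet_day_prob
    c = spec.wet_persistence if pi > 0 else 0.0
    p_wd = pi * (1.0 - c)          # P(wet | dry yesterday)
    p_ww = min(p_wd + c, 1.0)      # P(wet | wet yesterday)

    # southern hemisphere peaks in January instead of July
    peak_doy = 197 if spec.latitude >= 0 else 15

    days: list[DailyWeather] = []
    wet_prev = rng.random() < pi
    t_noise = 0.0
    for k in range(n_days):
        date = start_date + datetime.timedelta(days=k)
        doy = date.timetuple().tm_yday
        p_wet = p_ww if wet_prev else p_wd
        wet = rng.random() < p_wet
        precip = float(rng.exponential(spec.wet_day_mean_depth)) if wet and spec.wet_day_mean_depth > 0 else 0.0
        if wet and spec.wet_day_mean_depth > 0:
            precip = round(precip, 2)
            wet = precip > 0
        else:
            precip = 0.0

        t_noise = 0.7 * t_noise + rng.normal(0.0, 1.5)
        tmean = (
            spec.t_annual_mean
            + spec.t_annual_amplitude * math.cos(2.0 * math.pi * (doy - peak_doy) / 365.25)
            + t_noise
        )
        dtr = spec.t_daily_range * (0.6 if wet else 1.0)
        tmin = tmean - dtr / 2.0
        tmax = tmean + dtr / 2.0

        ra = extraterrestrial_radiation(spec.latitude, doy)
        rso = clear_sky_radiation(ra, spec.elevation)
        clear_frac = rng.uniform(0.35, 0.6) if wet else rng.uniform(0.75, 1.0)
        rs = rso * clear_frac

        rh = spec.rh_baseline - 1.2 * t_noise + (12.0 if wet else 0.0) + rng.normal(0.0, 4.0)
        rh_mean = float(min(max(rh, 10.0), 100.0))
        rh_min = float(min(max(rh_mean - 18.0, 5.0), 100.0))

        days.append(
            DailyWeather(
                date=date, tmin=round(tmin, 2), tmax=round(tmax, 2),
                rh_mean=round(rh_mean, 1), rh_min=round(rh_min, 1),
                rs=round(rs, 3), u2=None, precip=precip,
            )
        )
        wet_prev = wet
    return days


def fixture_scenarios(seed: int = 0) -> dict:
    """Named, complete, runnable scenarios spanning the main regimes.

    Covers a humid rain-fed cereal, an arid drip-irrigated root crop, an
    arid sprinkler-irrigated (rain gun) cereal, and a drought control with
    no water input at all.  Returns a dict of run configurations keyed by
    scenario name.
    """
    from .config import (  # deferred: config imports this module
        CropSpec, IrrigationSpec, RunConfig, SoilSpec, WeatherSource,
    )
    from .meteorology import SiteInfo
    from .soil import SoilComposition

    scenarios = {
        "humid_rainfed_wheat": RunConfig(
            name="humid_rainfed_wheat",
            site=SiteInfo(latitude=10.0, elevation=50.0),
            soil=SoilSpec(composition=SoilComposition(sand_frac=0.30, clay_frac=0.25, om_frac=0.03)),
            crop=CropSpec(name="wheat"),
            sowing=datetime.date(2015, 5, 5),
            harvest=datetime.date(2015, 9, 1),
            initial_moisture="mid",
            irrigation=None,
            yield_kg_ha=4000.0,
            weather=WeatherSource(regime=ClimateRegime.HUMID, seed=seed),
        ),
        "arid_drip_potato": RunConfig(
            name="arid_drip_potato",
            site=SiteInfo(latitude=32.0, elevation=300.0),
            soil=SoilSpec(composition=SoilComposition(sand_frac=0.55, clay_frac=0.15, om_frac=0.015)),
            crop=CropSpec(name="potato"),
            sowing=datetime.date(2015, 3, 15),
            harvest=datetime.date(2015, 7, 22),
            initial_moisture="mid",
            irrigation=IrrigationSpec(
                method="drip", total_depth=300.0, n_events=15,
                start=datetime.date(2015, 4, 5), end=datetime.date(2015, 7, 5),
            ),
            yield_kg_ha=40000.0,
            weather=WeatherSource(regime=ClimateRegime.ARID, seed=seed),
        ),
        "arid_raingun_maize": RunConfig(
            name="arid_raingun_maize",
            site=SiteInfo(latitude=32.0, elevation=300.0),
            soil=SoilSpec(composition=SoilComposition(sand_frac=0.40, clay_frac=0.22, om_frac=0.02)),
            crop=CropSpec(name="maize"),
            sowing=datetime.date(2015, 4, 15),
            harvest=datetime.date(2015, 9, 11),
            initial_moisture="mid",
            irrigation=IrrigationSpec(
                method="rain_gun", total_depth=400.0, n_events=8,
                start=datetime.date(2015, 5, 15), end=datetime.date(2015, 8, 25),
            ),
            yield_kg_ha=9000.0,
            weather=WeatherSource(regime=ClimateRegime.ARID, seed=seed),
        ),
        "drought_control": RunConfig(
            name="drought_control",
            site=SiteInfo(latitude=32.0, elevation=300.0),
            soil=SoilSpec(composition=SoilComposition(sand_frac=0.40, clay_frac=0.22, om_frac=0.02)),
            crop=CropSpec(name="maize"),
            sowing=datetime.date(2015, 4, 15),
            harvest=datetime.date(2015, 9, 11),
            initial_moisture="low",
            irrigation=None,
            yield_kg_ha=3000.0,
            weather=WeatherSource(
                climate=climate_preset(ClimateRegime.ARID, seed=seed, wet_day_prob=0.0),
                seed=seed,
            ),
        ),
    }
    return scenarios
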