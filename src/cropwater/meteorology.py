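"""Reference evapotranspiration and its meteorological inputs.

Implements the FAO56 daily Penman-Monteith formulation for a standardized
well-watered grass reference surface (height 0.12 m, surface resistance
70 s m^-1, albedo 0.23), together with the supporting chain: Tetens
saturation vapour pressure, the slope of the saturation curve, the
psychrometric constant from elevation, extraterrestrial and clear-sky
radiation, and the Stefan-Boltzmann net longwave term.

Wind speed is not a user input: a fixed global average of 2 m s^-1 is used
unless a measured value is supplied, and the soil heat flux G is taken as
zero at the daily time step.
"""

from __future__ import annotations

import datetime
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

logger = logging.getLogger(__name__)

#: Solar constant, MJ m^-2 min^-1.
SOLAR_CONSTANT = 0.0820
#: Stefan-Boltzmann constant, MJ K^-4 m^-2 d^-1.
STEFAN_BOLTZMANN = 4.903e-9
#: Albedo of the grass reference surface.
ALBEDO = 0.23
#: Fixed global-average wind speed at 2 m, m s^-1.
DEFAULT_WIND = 2.0
#: Default Hargreaves radiation adjustment coefficient (interior locations).
KRS_INTERIOR = 0.16
#: Hargreaves coefficient for coastal locations.
KRS_COASTAL = 0.19

WEATHER_COLUMNS = ["date", "tmin", "tmax", "rh_mean", "rh_min", "rs", "u2", "precip"]


class DailyWeather(BaseModel):
    """One day of meteorological forcing.

    Temperatures in degC, humidities in %, solar radiation ``rs`` in
    MJ m^-2 d^-1, wind ``u2`` in m s^-1 at 2 m height, precipitation in
    mm d^-1.  ``rs`` and ``u2`` are optional; at least one of ``rh_mean``
    and ``rh_min`` must be present.
    """

    date: datetime.date
    tmin: float
    tmax: float
    rh_mean: Optional[float] = None
    rh_min: Optional[float] = None
    rs: Optional[float] = None
    u2: Optional[float] = None
    precip: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "DailyWeather":
        if self.tmin > self.tmax:
            raise ValueError(f"{self.date}: tmin ({self.tmin}) exceeds tmax ({self.tmax})")
        for name in ("rh_mean", "rh_min"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{self.date}: {name}={v} outside [0, 100]%")
        if self.rh_mean is None and self.rh_min is None:
            raise ValueError(f"{self.date}: at least one of rh_mean/rh_min is required")
        if self.rs is not None and self.rs < 0:
            raise ValueError(f"{self.date}: rs={self.rs} negative")
        if self.precip < 0:
            raise ValueError(f"{self.date}: precip={self.precip} negative")
        if self.u2 is not None and self.u2 < 0:
            raise ValueError(f"{self.date}: u2={self.u2} negative")
        return self

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmin + self.tmax)


class SiteInfo(BaseModel):
    """Field location: latitude in decimal degrees, elevation in metres."""

    latitude: float
    elevation: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "SiteInfo":
        if abs(self.latitude) > 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        return self


@dataclass(frozen=True)
class MetDerived:
    """Derived meteorological terms entering the Penman-Monteith equation.

    ``delta`` (kPa degC^-1) is the slope of the saturation vapour pressure
    curve at mean temperature, ``gamma`` (kPa degC^-1) the psychrometric
    constant, ``es``/``ea`` (kPa) saturation and actual vapour pressure,
    ``vpd`` their deficit, ``rn`` net radiation (MJ m^-2 d^-1) and ``g``
    the soil heat flux, fixed at zero for daily steps.
    """

    delta: float
    gamma: float
    es: float
    ea: float
    vpd: float
    rn: float
    g: float = 0.0


def saturation_vapour_pressure(t: float) -> float:
    """Tetens saturation vapour pressure (kPa) at air temperature t (degC)."""
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def slope_vapour_curve(t: float) -> float:
    """Slope of the saturation vapour pressure curve (kPa degC^-1) at t."""
    return 4098.0 * saturation_vapour_pressure(t) / (t + 237.3) ** 2


def atmospheric_pressure(elevation: float) -> float:
    """Standard-atmosphere pressure (kPa) at the given elevation (m)."""
    return 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26


def psychrometric_constant(elevation: float) -> float:
    """Psychrometric constant gamma (kPa degC^-1) from elevation."""
    return 0.665e-3 * atmospheric_pressure(elevation)


def vapour_terms(
    tmin: float,
    tmax: float,
    rh_mean: Optional[float] = None,
    rh_min: Optional[float] = None,
) -> tuple[float, float, float, float]:
    """Saturation/actual vapour pressure, deficit and curve slope.

    ``es`` is the mean of the saturation vapour pressure at tmax and tmin.
    Actual vapour pressure prefers the minimum-humidity route
    ``ea = es(tmax) * rh_min / 100`` (daily minimum humidity occurs near the
    daily maximum temperature) and falls back to ``ea = rh_mean/100 * es``.

    Returns (es, ea, vpd, delta), all vapour pressures in kPa.
    """
    if tmin > tmax:
        raise ValueError(f"tmin ({tmin}) exceeds tmax ({tmax})")
    for name, v in (("rh_mean", rh_mean), ("rh_min", rh_min)):
        if v is not None and not (0.0 <= v <= 100.0):
            raise ValueError(f"{name}={v} outside [0, 100]%")
    es = 0.5 * (saturation_vapour_pressure(tmax) + saturation_vapour_pressure(tmin))
    if rh_min is not None:
        ea = saturation_vapour_pressure(tmax) * rh_min / 100.0
    elif rh_mean is not None:
        ea = es * rh_mean / 100.0
    else:
        raise ValueError("either rh_mean or rh_min must be provided")
    vpd = max(es - ea, 0.0)
    delta = slope_vapour_curve(0.5 * (tmin + tmax))
    return es, ea, vpd, delta


def extraterrestrial_radiation(latitude: float, doy: int) -> float:
    """Daily extraterrestrial radiation Ra (MJ m^-2 d^-1).

    Polar night (sun never above the horizon) yields 0; continuous daylight
    is handled by clamping the sunset-hour angle argument.
    """
    phi = math.radians(latitude)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    decl = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    x = -math.tan(phi) * math.tan(decl)
    ws = math.acos(min(1.0, max(-1.0, x)))
    ra = (
        24.0 * 60.0 / math.pi * SOLAR_CONSTANT * dr
        * (ws * math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(decl) * math.sin(ws))
    )
    return max(ra, 0.0)


def clear_sky_radiation(ra: float, elevation: float) -> float:
    """Clear-sky shortwave radiation Rso (MJ m^-2 d^-1)."""
    return (0.75 + 2e-5 * elevation) * ra


def solar_from_temperature(tmin: float, tmax: float, ra: float, k_rs: float = KRS_INTERIOR) -> float:
    """Hargreaves-type solar radiation estimate from the diurnal range."""
    return k_rs * math.sqrt(max(tmax - tmin, 0.0)) * ra


def net_radiation(
    rs: float,
    tmin: float,
    tmax: float,
    ea: float,
    site: SiteInfo,
    doy: int,
) -> float:
    """Net radiation Rn (MJ m^-2 d^-1) at the reference surface.

    Shortwave gain is (1 - albedo) * rs; longwave loss follows the FAO56
    Stefan-Boltzmann formulation with the relative shortwave ratio rs/rso
    clamped to [0.25, 1].  If measured rs exceeds the clear-sky value the
    ratio is clamped to 1 and a warning is logged.
    """
    if rs < 0:
        raise ValueError(f"rs={rs} negative")
    ra = extraterrestrial_radiation(site.latitude, doy)
    rso = clear_sky_radiation(ra, site.elevation)
    if rso <= 0.0:
        # Polar night: no shortwave reference; assume a clear sky for the
        # longwave term so the day loses energy radiatively.
        ratio = 1.0
        if rs > 0:
            logger.warning("rs=%.2f with zero clear-sky radiation (doy=%d); ratio clamped to 1", rs, doy)
    else:
        ratio = rs / rso
        if ratio > 1.0:
            logger.warning("rs=%.2f exceeds clear-sky %.2f (doy=%d); ratio clamped to 1", rs, rso, doy)
            ratio = 1.0
        ratio = max(ratio, 0.25)
    tmax_k4 = (tmax + 273.16) ** 4
    tmin_k4 = (tmin + 273.16) ** 4
    rnl = (
        STEFAN_BOLTZMANN
        * 0.5 * (tmax_k4 + tmin_k4)
        * (0.34 - 0.14 * math.sqrt(max(ea, 0.0)))
        * (1.35 * ratio - 0.35)
    )
    return (1.0 - ALBEDO) * rs - rnl


def met_derived(
    weather: DailyWeather,
    site: SiteInfo,
    k_rs: float = KRS_INTERIOR,
) -> MetDerived:
    """Assemble all derived meteorological terms for one day.

    When solar radiation is missing it is estimated from the diurnal
    temperature range (a warning is logged), so the model still runs on
    temperature-plus-humidity data.
    """
    es, ea, vpd, delta = vapour_terms(weather.tmin, weather.tmax, weather.rh_mean, weather.rh_min)
    doy = weather.date.timetuple().tm_yday
    rs = weather.rs
    if rs is None:
        ra = extraterrestrial_radiation(site.latitude, doy)
        rs = solar_from_temperature(weather.tmin, weather.tmax, ra, k_rs)
        logger.warning("%s: solar radiation missing, estimated %.2f MJ m-2 d-1 from temperature range",
                       weather.date, rs)
    rn = net_radiation(rs, weather.tmin, weather.tmax, ea, site, doy)
    gamma = psychrometric_constant(site.elevation)
    return MetDerived(delta=delta, gamma=gamma, es=es, ea=ea, vpd=vpd, rn=rn)


def reference_et0(weather: DailyWeather, met: MetDerived) -> float:
    """Daily reference evapotranspiration ET0 (mm d^-1), Penman-Monteith.

    ET0 = [0.408 Delta (Rn - G) + gamma 900/(T+273) u2 VPD]
          / [Delta + gamma (1 + 0.34 u2)]

    with T the daily mean temperature and u2 defaulting to the fixed
    2 m s^-1 global average.  The result is clamped at zero: condensation
    days are treated as zero reference demand.
    """
    for name, v in (("delta", met.delta), ("gamma", met.gamma), ("vpd", met.vpd), ("rn", met.rn)):
        if not math.isfinite(v):
            raise ValueError(f"non-finite {name} on {weather.date}")
    u2 = weather.u2 if weather.u2 is not None else DEFAULT_WIND
    t = weather.tmean
    num = 0.408 * met.delta * (met.rn - met.g) + met.gamma * (900.0 / (t + 273.0)) * u2 * met.vpd
    den = met.delta + met.gamma * (1.0 + 0.34 * u2)
    return max(num / den, 0.0)


def et0_for_day(weather: DailyWeather, site: SiteInfo, k_rs: float = KRS_INTERIOR) -> float:
    """Convenience wrapper: derived terms plus ET0 in one call."""
    return reference_et0(weather, met_derived(weather, site, k_rs=k_rs))


def et0_series(days: Sequence[DailyWeather], site: SiteInfo, k_rs: float = KRS_INTERIOR) -> np.ndarray:
    """Vector of daily ET0 over a sequence of weather days."""
    return np.array([et0_for_day(d, site, k_rs=k_rs) for d in days], dtype=float)


# ---------------------------------------------------------------------------
# Weather CSV interface
# ---------------------------------------------------------------------------

def weather_to_frame(days: Sequence[DailyWeather]) -> pd.DataFrame:
    """Represent a weather series as a DataFrame with the standard columns."""
    return pd.DataFrame(
        {
            "date": [d.date for d in days],
            "tmin": [d.tmin for d in days],
            "tmax": [d.tmax for d in days],
            "rh_mean": [d.rh_mean for d in days],
            "rh_min": [d.rh_min for d in days],
            "rs": [d.rs for d in days],
            "u2": [d.u2 for d in days],
            "precip": [d.precip for d in days],
        }
    )


def frame_to_weather(frame: pd.DataFrame, source: str = "<frame>") -> list[DailyWeather]:
    """Validate a weather DataFrame row by row into DailyWeather records.

    Raises ValueError naming the offending (1-based, header-inclusive) line
    on the first invalid row; dates must be strictly increasing and gap-free.
    """
    missing = [c for c in ("date", "tmin", "tmax", "precip") if c not in frame.columns]
    if missing:
        raise ValueError(f"{source}: missing required columns {missing}")
    days: list[DailyWeather] = []
    prev: Optional[datetime.date] = None
    for pos, (_, row) in enumerate(frame.iterrows()):
        line = pos + 2  # header is line 1
        kwargs = {}
        for col in WEATHER_COLUMNS:
            v = row.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
                continue
            kwargs[col] = v
        if "date" in kwargs:
            d = kwargs["date"]
            if isinstance(d, str):
                kwargs["date"] = datetime.date.fromisoformat(d)
            elif isinstance(d, pd.Timestamp):
                kwargs["date"] = d.date()
        try:
            day = DailyWeather(**kwargs)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{source}, line {line}: {exc}") from exc
        if prev is not None:
            if day.date <= prev:
                raise ValueError(f"{source}, line {line}: dates not strictly increasing ({prev} -> {day.date})")
            if (day.date - prev).days != 1:
                raise ValueError(f"{source}, line {line}: gap in dates ({prev} -> {day.date})")
        prev = day.date
        days.append(day)
    return days


def read_weather_csv(path) -> list[DailyWeather]:
    """Read the standard weather CSV (header ``date,tmin,tmax,rh_mean,
    rh_min,rs,u2,precip``; ISO-8601 dates; empty cells mean missing)."""
    frame = pd.read_csv(path)
    return frame_to_weather(frame, source=str(path))


def write_weather_csv(days: Sequence[DailyWeather], path) -> None:
    """Write a weather series to CSV with the standard header."""
    weather_to_frame(days).to_csv(path, index=False)
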