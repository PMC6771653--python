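"""Crop phenology: stage lengths, the Kc curve, rooting depth and LAI.

The single crop coefficient Kc follows the classic trapezoid — a constant
initial value, a linear ramp over the development stage, a mid-season
plateau, and a linear decline through the late season.  Three adjustments
are applied to the tabulated values:

* the initial Kc is recomputed from a two-stage (energy-limited then
  falling-rate) bare-soil evaporation estimate driven by the wetting
  frequency of the surface, the initial-stage evaporative demand, the soil
  texture, and the fraction of the surface wetted by irrigation;
* mid-season (and, for crops that are not left to dry out, end-season) Kc
  is corrected for minimum humidity and crop height — wind is fixed at the
  2 m s^-1 global average, so the wind term vanishes identically;
* stage lengths are rescaled proportionally to the user's growing period.

Rooting depth grows linearly from an initial to the maximum depth over the
initial plus development stages; leaf area index grows linearly from 0 to
0.1 m2 m-2 over the initial stage and on to its crop maximum over the
development stage.  Default parameters ship as a plain-text table
(``data/crops.csv``) and every field can be overridden per run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from .soil import TextureClass

#: Total evaporable / readily evaporable water (mm) of the surface layer by
#: texture group (midpoints of the usual tabulated ranges).
TEW_REW = {
    TextureClass.COARSE: (6.0, 2.0),
    TextureClass.MEDIUM: (9.0, 4.0),
    TextureClass.FINE: (11.0, 5.0),
}

KC_INI_FLOOR = 0.05
KC_INI_CEILING = 1.15
#: A day counts as a surface-wetting event above this depth (mm).
WETTING_EVENT_THRESHOLD = 2.0


class CropParameters(BaseModel):
    """Tabulated parameters of one crop.

    Kc values are dimensionless; stage lengths in days; heights and rooting
    depths in metres; ``p_tab`` is the soil water depletion fraction below
    which no stress occurs; ``lai_max`` in m2 m-2.
    """

    name: str
    kc_ini: float
    kc_mid: float
    kc_end: float
    l_ini: int
    l_dev: int
    l_mid: int
    l_late: int
    h_max: float
    zr_ini: float
    zr_max: float
    p_tab: float
    lai_max: float

    @model_validator(mode="after")
    def _check(self) -> "CropParameters":
        for name in ("kc_ini", "kc_mid", "kc_end"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.5):
                raise ValueError(f"{name}={v} outside (0, 1.5]")
        for name in ("l_ini", "l_dev", "l_mid", "l_late"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.zr_ini > self.zr_max:
            raise ValueError(f"zr_ini ({self.zr_ini}) exceeds zr_max ({self.zr_max})")
        if not (0.0 < self.p_tab < 1.0):
            raise ValueError(f"p_tab={self.p_tab} outside (0, 1)")
        if self.lai_max <= 0 or self.h_max <= 0 or self.zr_ini <= 0:
            raise ValueError("h_max, zr_ini and lai_max must be positive")
        return self

    @property
    def default_stage_lengths(self) -> tuple[int, int, int, int]:
        return (self.l_ini, self.l_dev, self.l_mid, self.l_late)


def load_crop_table(path=None) -> dict[str, CropParameters]:
    """Load the crop parameter table (the packaged defaults, or a
    user-supplied CSV with the same columns)."""
    if path is None:
        with resources.files("cropwater.data").joinpath("crops.csv").open() as fh:
            frame = pd.read_csv(fh)
    else:
        frame = pd.read_csv(path)
    table = {}
    for _, row in frame.iterrows():
        params = CropParameters(**row.to_dict())
        table[params.name] = params
    return table


def get_crop(name: str, overrides: Optional[dict] = None, path=None) -> CropParameters:
    """Fetch a crop by name, optionally overriding any parameter."""
    table = load_crop_table(path)
    if name not in table:
        raise KeyError(f"unknown crop {name!r}; available: {', '.join(sorted(table))}")
    crop = table[name]
    if overrides:
        crop = crop.model_copy(update=dict(overrides))
        crop = CropParameters(**crop.model_dump())  # re-validate
    return crop


def scale_stages(crop: CropParameters, total_days: int) -> tuple[int, int, int, int]:
    """Rescale the default stage lengths to the user's growing period.

    Each stage is rounded from its default fraction of the total; the
    rounding residual is absorbed by the longest stage so the four lengths
    sum exactly to ``total_days`` and each stays at least one day.
    """
    if total_days < 4:
        raise ValueError(f"growing period of {total_days} days is too short (minimum 4)")
    defaults = crop.default_stage_lengths
    total_default = sum(defaults)
    scaled = [max(1, round(d / total_default * total_days)) for d in defaults]
    longest = int(np.argmax(scaled))
    scaled[longest] += total_days - sum(scaled)
    if scaled[longest] < 1:
        raise ValueError(f"cannot fit four stages of at least one day into {total_days} days")
    return tuple(scaled)  # type: ignore[return-value]


def _kc_ini_single(et0: float, wetting_interval: float, tew: float, rew: float) -> float:
    """Mean initial-stage Kc for a uniformly wetted surface.

    Two-stage evaporation between wettings: an energy-limited stage at
    1.15 * ET0 until the readily evaporable water REW is gone, then a
    falling-rate stage that asymptotes to the total evaporable water TEW.
    The mean Kc over one wetting interval of ``wetting_interval`` days is
    the evaporated depth divided by the cumulative reference demand.
    """
    if wetting_interval < 1:
        raise ValueError(f"wetting_interval={wetting_interval} must be >= 1 day")
    if et0 <= 1e-9:
        return KC_INI_CEILING
    eso = 1.15 * et0
    t1 = rew / eso
    tw = float(wetting_interval)
    if tw <= t1:
        return KC_INI_CEILING
    evaporated = tew - (tew - rew) * math.exp(
        -(tw - t1) * eso * (1.0 + rew / (tew - rew)) / tew
    )
    evaporated = min(evaporated, tew)
    return evaporated / (tw * et0)


def kc_ini_adjust(
    et0_ini_mean: float,
    wetting_interval: float,
    texture_class: TextureClass,
    fw: float = 1.0,
    precip_interval: Optional[float] = None,
) -> float:
    """Initial-stage Kc from wetting frequency, demand, texture and method.

    ``wetting_interval`` is the mean interval (days) between wetting events
    of the irrigated fraction (precipitation plus irrigation).  For
    partial-wetting methods (``fw`` < 1, e.g. drip at 0.35 or furrow at
    0.5) the result is the fw-weighted combination of the wetted-fraction
    value and the value for the remainder, which only precipitation wets
    (``precip_interval``; if None, the remainder is treated as unwetted).
    Clamped to [0.05, 1.15].
    """
    if not (0.0 < fw <= 1.0):
        raise ValueError(f"fw={fw} outside (0, 1]")
    tew, rew = TEW_REW[TextureClass(texture_class)]
    kc_wet = _kc_ini_single(et0_ini_mean, wetting_interval, tew, rew)
    if fw >= 1.0:
        kc = kc_wet
    else:
        if precip_interval is None:
            kc_dry = KC_INI_FLOOR
        else:
            kc_dry = _kc_ini_single(et0_ini_mean, precip_interval, tew, rew)
        kc = fw * kc_wet + (1.0 - fw) * kc_dry
    return min(max(kc, KC_INI_FLOOR), KC_INI_CEILING)


def mean_wetting_interval(depths, stage_length: int,
                          threshold: float = WETTING_EVENT_THRESHOLD) -> float:
    """Mean interval (days) between surface-wetting events.

    ``depths`` is the per-day wetting depth over the initial stage; a day
    with at least ``threshold`` mm counts as an event.  With fewer than two
    events the interval defaults to the stage length (a dry surface).
    """
    days = [i for i, d in enumerate(depths) if d >= threshold]
    if len(days) < 2:
        return float(max(stage_length, 1))
    return float(np.mean(np.diff(days)))


def kc_climate_adjust(kc_tab: float, rh_min_mean: float, h: float) -> float:
    """Humidity/height correction of mid- and end-season Kc.

    kc = kc_tab + [0.04 (u2 - 2) - 0.004 (RHmin - 45)] (h/3)^0.3 with the
    wind speed fixed at u2 = 2 m s^-1, so the wind term is identically
    zero.  RHmin is clamped to the [20, 80]% validity range and h to
    [0.1, 10] m.
    """
    if h <= 0:
        raise ValueError(f"crop height h={h} must be positive")
    rh = min(max(rh_min_mean, 20.0), 80.0)
    h = min(max(h, 0.1), 10.0)
    u2 = 2.0
    return kc_tab + (0.04 * (u2 - 2.0) - 0.004 * (rh - 45.0)) * (h / 3.0) ** 0.3


def kc_at_day(
    day_index: int,
    stages: tuple[int, int, int, int],
    kc_ini: float,
    kc_mid: float,
    kc_end: float,
) -> float:
    """Kc on 1-based season day ``day_index``: constant in the initial
    stage, linear to kc_mid across development, a mid-season plateau, then
    linear to kc_end, reached on the final day."""
    l_ini, l_dev, l_mid, l_late = stages
    total = l_ini + l_dev + l_mid + l_late
    if not (1 <= day_index <= total):
        raise ValueError(f"day {day_index} outside season of {total} days")
    if day_index <= l_ini:
        return kc_ini
    if day_index <= l_ini + l_dev:
        frac = (day_index - l_ini) / l_dev
        return kc_ini + frac * (kc_mid - kc_ini)
    if day_index <= l_ini + l_dev + l_mid:
        return kc_mid
    frac = (day_index - l_ini - l_dev - l_mid) / l_late
    return kc_mid + frac * (kc_end - kc_mid)


def root_and_lai_at_day(
    day_index: int,
    stages: tuple[int, int, int, int],
    crop: CropParameters,
) -> tuple[float, float]:
    """Rooting depth (m) and LAI (m2 m-2) on 1-based day ``day_index``.

    Zr ramps linearly from zr_ini on day 1 to zr_max on the last day of the
    development stage, then stays constant.  LAI ramps 0 -> 0.1 over the
    initial stage and 0.1 -> lai_max over development, then stays constant.
    """
    l_ini, l_dev, l_mid, l_late = stages
    total = l_ini + l_dev + l_mid + l_late
    if not (1 <= day_index <= total):
        raise ValueError(f"day {day_index} outside season of {total} days")
    end_dev = l_ini + l_dev
    if day_index >= end_dev:
        zr = crop.zr_max
    elif end_dev == 1:
        zr = crop.zr_max
    else:
        zr = crop.zr_ini + (crop.zr_max - crop.zr_ini) * (day_index - 1) / (end_dev - 1)
    if day_index <= l_ini:
        lai = 0.1 if l_ini == 1 else 0.1 * (day_index - 1) / (l_ini - 1)
    elif day_index <= end_dev:
        lai = 0.1 + (crop.lai_max - 0.1) * (day_index - l_ini) / l_dev
    else:
        lai = crop.lai_max
    return zr, lai


@dataclass(frozen=True)
class SeasonPhenology:
    """Per-day phenology trajectories for one growing season."""

    stages: tuple[int, int, int, int]
    kc: np.ndarray
    zr: np.ndarray
    lai: np.ndarray
    kc_ini: float
    kc_mid: float
    kc_end: float

    @property
    def total_days(self) -> int:
        return int(sum(self.stages))


def build_phenology(
    crop: CropParameters,
    total_days: int,
    kc_ini: Optional[float] = None,
    rh_min_mid: float = 45.0,
    rh_min_late: float = 45.0,
) -> SeasonPhenology:
    """Assemble the season's Kc, Zr and LAI curves.

    ``kc_ini`` replaces the tabulated initial value when the wetting-driven
    estimate is available.  Mid-season Kc is always climate-adjusted;
    end-season Kc only when the tabulated value is at least 0.45 (crops
    harvested green rather than left to dry).
    """
    stages = scale_stages(crop, total_days)
    kci = crop.kc_ini if kc_ini is None else kc_ini
    kcm = kc_climate_adjust(crop.kc_mid, rh_min_mid, crop.h_max)
    if crop.kc_end >= 0.45:
        kce = kc_climate_adjust(crop.kc_end, rh_min_late, crop.h_max)
    else:
        kce = crop.kc_end
    days = np.arange(1, total_days + 1)
    kc = np.array([kc_at_day(d, stages, kci, kcm, kce) for d in days])
    zr_lai = [root_and_lai_at_day(d, stages, crop) for d in days]
    zr = np.array([z for z, _ in zr_lai])
    lai = np.array([l for _, l in zr_lai])
    return SeasonPhenology(stages=stages, kc=kc, zr=zr, lai=lai,
                           kc_ini=kci, kc_mid=kcm, kc_end=kce)
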