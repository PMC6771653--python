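"""Daily root-zone water balance with interception, runoff and percolation.

The root zone is a tipping bucket tracked as depletion Dr (mm below field
capacity).  Each day, in order: the root zone deepens (new storage carries
the season-initial relative depletion), the canopy intercepts part of the
rain and of above-canopy irrigation, the soil sheds surface runoff scaled
by its relative wetness, the remaining water infiltrates, any excess below
zero depletion drains the same day as deep percolation, and finally the
crop transpires at ETa = ET0 * Kc * Ks where the stress coefficient Ks
falls linearly from 1 to 0 as depletion moves from the readily available
water (RAW) to the total available water (TAW).

Capillary rise and lateral flow are taken as zero, so the model applies
only where those terms are negligible (no shallow groundwater, level
fields).

Irrigation methods differ in the wetted soil fraction (drip 0.35, furrow
0.5, flood/pivot/rain gun 1.0) and in whether water is applied above the
canopy (pivot and rain gun), which exposes it to interception.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from .crop import (
    CropParameters,
    SeasonPhenology,
    build_phenology,
    kc_ini_adjust,
    mean_wetting_interval,
    scale_stages,
)
from .meteorology import (
    DailyWeather,
    SiteInfo,
    et0_for_day,
    saturation_vapour_pressure,
)
from .soil import SoilHydraulics, adjusted_depletion_fraction, storage_capacities

#: Interception capacity coefficient, mm d-1 per unit LAI.
INTERCEPTION_A = 0.25


class IrrigationMethod(str, Enum):
    DRIP = "drip"
    FLOOD = "flood"
    PIVOT = "pivot"
    RAIN_GUN = "rain_gun"
    FURROW = "furrow"

    @property
    def wetted_fraction(self) -> float:
        """Fraction of the soil surface wetted by one application."""
        return {"drip": 0.35, "furrow": 0.5}.get(self.value, 1.0)

    @property
    def above_canopy(self) -> bool:
        """Whether water passes over the canopy (subject to interception)."""
        return self in (IrrigationMethod.PIVOT, IrrigationMethod.RAIN_GUN)


class MoistureClass(str, Enum):
    """Initial soil moisture: high = at field capacity; mid = two thirds of
    the available water capacity filled; low = one third filled."""

    HIGH = "high"
    MID = "mid"
    LOW = "low"


class TimingClass(str, Enum):
    """Within-month timing classes standing for the 5th, 15th and 25th."""

    EARLY = "early"
    MID = "mid"
    LATE = "late"


def resolve_date_class(month: int, year: int, timing: TimingClass | str) -> datetime.date:
    """Map (month, year, early/mid/late) to the 5th/15th/25th of the month."""
    day = {TimingClass.EARLY: 5, TimingClass.MID: 15, TimingClass.LATE: 25}[TimingClass(timing)]
    if not (1 <= month <= 12):
        raise ValueError(f"invalid month {month}")
    return datetime.date(year, month, day)


class IrrigationPlan(BaseModel):
    """A season's irrigation: method, total depth (mm), number of events
    and the application period (dates inclusive)."""

    method: IrrigationMethod
    total_depth: float = 0.0
    n_events: int = 1
    start_date: Optional[datetime.date] = None
    end_date: Optional[datetime.date] = None

    @model_validator(mode="after")
    def _check(self) -> "IrrigationPlan":
        if self.total_depth < 0:
            raise ValueError(f"total_depth={self.total_depth} negative")
        if self.total_depth > 0:
            if self.n_events < 1:
                raise ValueError("n_events must be >= 1 when total_depth > 0")
            if self.start_date is None or self.end_date is None:
                raise ValueError("irrigation period (start_date, end_date) is required")
            if self.start_date > self.end_date:
                raise ValueError(f"start {self.start_date} after end {self.end_date}")
        return self


@dataclass(frozen=True)
class IrrigationEvent:
    date: datetime.date
    depth: float
    above_canopy: bool
    fw: float


def expand_irrigation(plan: IrrigationPlan) -> list[IrrigationEvent]:
    """Distribute the total depth equally over evenly spaced event dates.

    ``n_events`` events of depth total/n at dates evenly spaced from start
    to end inclusive (a single event falls on the start date).
    """
    if plan.total_depth <= 0:
        return []
    depth = plan.total_depth / plan.n_events
    span = (plan.end_date - plan.start_date).days
    events = []
    for k in range(plan.n_events):
        offset = 0 if plan.n_events == 1 else round(k * span / (plan.n_events - 1))
        events.append(
            IrrigationEvent(
                date=plan.start_date + datetime.timedelta(days=offset),
                depth=depth,
                above_canopy=plan.method.above_canopy,
                fw=plan.method.wetted_fraction,
            )
        )
    return events


def initial_depletion(moisture_class: MoistureClass | str, taw0: float) -> float:
    """Initial root-zone depletion from the user's moisture class.

    high -> at field capacity (no depletion); mid -> 2/3 of the available
    capacity filled (depletion TAW/3); low -> 1/3 filled (2 TAW/3).
    """
    if taw0 <= 0:
        raise ValueError(f"taw0={taw0} must be positive")
    cls = MoistureClass(moisture_class)
    return {MoistureClass.HIGH: 0.0,
            MoistureClass.MID: taw0 / 3.0,
            MoistureClass.LOW: 2.0 * taw0 / 3.0}[cls]


def interception(lai: float, p: float, i_above: float) -> tuple[float, float, float]:
    """Canopy interception of rain plus above-canopy irrigation (mm).

    Int = a LAI (1 - 1/(1 + b Ptot / (a LAI))) with a = 0.25 mm d-1 and
    soil cover fraction b = min(LAI/3, 1); the loss saturates at a*LAI.
    The total is attributed to rain and irrigation by their relative
    contributions; below-canopy irrigation is never intercepted.

    Returns (int_total, int_p, int_i).
    """
    if lai < 0 or p < 0 or i_above < 0:
        raise ValueError("interception inputs must be non-negative")
    ptot = p + i_above
    if lai <= 0.0 or ptot <= 0.0:
        return 0.0, 0.0, 0.0
    cap = INTERCEPTION_A * lai
    b = min(lai / 3.0, 1.0)
    int_total = cap * (1.0 - 1.0 / (1.0 + b * ptot / cap))
    return int_total, int_total * p / ptot, int_total * i_above / ptot


def runoff(ptot_surface: float, theta: float, soil: SoilHydraulics, beta: float = 1.0) -> float:
    """Surface runoff scaled by relative soil wetness.

    RO = Ptot * ((theta - theta_wp)/(theta_sat - theta_wp))^beta, clamped to
    [0, Ptot]: a soil at wilting point sheds nothing, a saturated soil sheds
    everything.  ``ptot_surface`` is all water reaching the soil surface
    (precipitation plus irrigation, after interception).
    """
    if ptot_surface < 0:
        raise ValueError(f"ptot_surface={ptot_surface} negative")
    rel = (theta - soil.theta_wp) / (soil.theta_sat - soil.theta_wp)
    rel = min(max(rel, 0.0), 1.0)
    return min(ptot_surface * rel ** beta, ptot_surface)


def water_stress(dr: float, taw: float, raw: float) -> float:
    """Stress coefficient Ks in [0, 1] from root-zone depletion: 1 while
    depletion stays within RAW, then (TAW - Dr)/(TAW - RAW)."""
    if not (0 <= raw < taw):
        raise ValueError(f"need 0 <= raw < taw, got raw={raw}, taw={taw}")
    if dr <= raw:
        return 1.0
    return min(max((taw - dr) / (taw - raw), 0.0), 1.0)


@dataclass(frozen=True)
class DailyState:
    """State and fluxes of one simulated day (depths in mm, theta in
    m3 m-3, zr in m)."""

    day_index: int
    date: datetime.date
    dr: float
    theta: float
    zr: float
    taw: float
    raw: float
    kc: float
    ks: float
    et0: float
    etc: float
    eta: float
    int_p: float
    int_i: float
    ro: float
    dp: float
    p: float
    i: float
    storage_added: float  # depletion carried into newly rooted soil (mm)

    @property
    def int_total(self) -> float:
        return self.int_p + self.int_i


@dataclass(frozen=True)
class DayForcing:
    """Forcing of one simulation day."""

    day_index: int
    date: datetime.date
    et0: float
    precip: float
    irrigation: float
    irrigation_above: float  # part of irrigation applied above the canopy
    kc: float
    zr: float
    lai: float


@dataclass
class BalanceOptions:
    """Numerical switches of the balance.

    ``runoff_beta`` is the exponent of the relative-wetness runoff term;
    ``adjust_depletion`` enables the daily demand adjustment of the
    depletion fraction p.
    """

    runoff_beta: float = 1.0
    adjust_depletion: bool = True


def step_day(
    prev: DailyState,
    forcing: DayForcing,
    soil: SoilHydraulics,
    p_tab: float,
    dr0_rel: float,
    options: BalanceOptions = BalanceOptions(),
) -> DailyState:
    """Advance the balance one day.

    Order of operations: (1) deepen the root zone, carrying the
    season-initial relative depletion into newly accessed soil;
    (2) intercept rain and above-canopy irrigation; (3) shed runoff from
    surface water using the previous day's soil wetness; (4) infiltrate;
    (5) drain any excess below zero depletion the same day (deep
    percolation); (6) transpire at ET0*Kc*Ks, capping depletion at TAW;
    (7) recompute the water content.
    """
    for name in ("et0", "precip", "irrigation", "kc", "zr", "lai"):
        v = getattr(forcing, name)
        if not np.isfinite(v):
            raise ValueError(f"non-finite {name} on {forcing.date}")

    awc = soil.available_water_capacity

    # (1) root growth: new storage enters at the season-initial status
    dz = max(forcing.zr - prev.zr, 0.0)
    added_taw = awc * dz * 1000.0
    storage_added = added_taw * dr0_rel
    dr = prev.dr + storage_added
    etc = forcing.et0 * forcing.kc
    p_frac = adjusted_depletion_fraction(p_tab, etc) if options.adjust_depletion else p_tab
    taw, raw = storage_capacities(soil, forcing.zr, p_frac)
    dr = min(dr, taw)

    # (2) interception
    int_total, int_p, int_i = interception(forcing.lai, forcing.precip, forcing.irrigation_above)

    # (3) runoff from all water reaching the surface, at yesterday's wetness
    surface = forcing.precip + forcing.irrigation - int_total
    ro = runoff(surface, prev.theta, soil, beta=options.runoff_beta)

    # (4) infiltration
    dr_interim = dr - (forcing.precip + forcing.irrigation - ro - int_total)

    # (5) same-day drainage of water above field capacity
    if dr_interim < 0.0:
        dp = -dr_interim
        dr_interim = 0.0
    else:
        dp = 0.0

    # (6) water stress and actual evapotranspiration
    ks = water_stress(dr_interim, taw, raw)
    eta = min(etc * ks, taw - dr_interim)
    dr_new = min(dr_interim + eta, taw)

    # (7) water content from depletion
    theta = soil.theta_fc - dr_new / (forcing.zr * 1000.0)

    return DailyState(
        day_index=forcing.day_index,
        date=forcing.date,
        dr=dr_new,
        theta=theta,
        zr=forcing.zr,
        taw=taw,
        raw=raw,
        kc=forcing.kc,
        ks=ks,
        et0=forcing.et0,
        etc=etc,
        eta=eta,
        int_p=int_p,
        int_i=int_i,
        ro=ro,
        dp=dp,
        p=forcing.precip,
        i=forcing.irrigation,
        storage_added=storage_added,
    )


@dataclass
class SeasonResult:
    """Full daily trace of one season plus the quantities needed for the
    footprint accounting."""

    states: list[DailyState]
    phenology: SeasonPhenology
    dr0: float
    taw0: float
    soil: SoilHydraulics
    crop: CropParameters

    @property
    def trace(self) -> pd.DataFrame:
        rows = []
        for s in self.states:
            rows.append({
                "day_index": s.day_index, "date": s.date, "dr": s.dr, "theta": s.theta,
                "zr": s.zr, "taw": s.taw, "raw": s.raw, "kc": s.kc, "ks": s.ks,
                "et0": s.et0, "etc": s.etc, "eta": s.eta, "int_p": s.int_p,
                "int_i": s.int_i, "ro": s.ro, "dp": s.dp, "p": s.p, "i": s.i,
                "storage_added": s.storage_added,
            })
        return pd.DataFrame(rows)

    def mass_balance_residual(self) -> float:
        """Season closure: inflows - outflows - storage change (mm);
        zero up to floating-point error by construction."""
        t = self.trace
        inflow = float((t["p"] + t["i"]).sum())
        outflow = float((t["eta"] + t["ro"] + t["dp"] + t["int_p"] + t["int_i"]).sum())
        dstorage = self.dr0 + float(t["storage_added"].sum()) - float(t["dr"].iloc[-1])
        return inflow - outflow - dstorage


def _rh_min_of_day(day: DailyWeather) -> float:
    """Daily minimum relative humidity, estimated from actual vapour
    pressure at the daily maximum temperature when not measured."""
    if day.rh_min is not None:
        return day.rh_min
    es_tmax = saturation_vapour_pressure(day.tmax)
    ea = (day.rh_mean or 50.0) / 100.0 * 0.5 * (
        es_tmax + saturation_vapour_pressure(day.tmin)
    )
    return min(max(100.0 * ea / es_tmax, 0.0), 100.0)


def simulate_season(
    weather: Sequence[DailyWeather],
    site: SiteInfo,
    soil: SoilHydraulics,
    crop: CropParameters,
    sowing: datetime.date,
    harvest: datetime.date,
    moisture_class: MoistureClass | str = MoistureClass.MID,
    irrigation: Optional[IrrigationPlan] = None,
    options: BalanceOptions = BalanceOptions(),
    k_rs: float = 0.16,
) -> SeasonResult:
    """Run the daily balance from sowing to harvest (inclusive).

    The weather series must cover the whole growing period without gaps.
    The initial-stage Kc is derived from the realized wetting schedule
    (rain plus irrigation events), and mid/late-season Kc from the mean
    minimum humidity over those stages.
    """
    if harvest <= sowing:
        raise ValueError(f"harvest {harvest} not after sowing {sowing}")
    total_days = (harvest - sowing).days + 1
    by_date = {d.date: d for d in weather}
    wanted = [sowing + datetime.timedelta(days=k) for k in range(total_days)]
    missing = [d for d in wanted if d not in by_date]
    if missing:
        head = ", ".join(str(d) for d in missing[:5])
        raise ValueError(f"weather missing for {len(missing)} day(s) of the season: {head}"
                         + ("..." if len(missing) > 5 else ""))
    season_weather = [by_date[d] for d in wanted]

    events = expand_irrigation(irrigation) if irrigation is not None else []
    for ev in events:
        if not (sowing <= ev.date <= harvest):
            raise ValueError(f"irrigation event on {ev.date} outside the growing period "
                             f"{sowing}..{harvest}")
    irr_by_date: dict[datetime.date, list[IrrigationEvent]] = {}
    for ev in events:
        irr_by_date.setdefault(ev.date, []).append(ev)

    et0 = np.array([et0_for_day(d, site, k_rs=k_rs) for d in season_weather])

    # --- phenology, with wetting-driven initial Kc and humidity-adjusted
    # mid/late Kc
    stages = scale_stages(crop, total_days)
    l_ini, l_dev, l_mid, l_late = stages
    ini_slice = slice(0, l_ini)
    fw = irrigation.method.wetted_fraction if irrigation is not None else 1.0
    wet_depths = []
    precip_depths = []
    for k in range(l_ini):
        date = wanted[k]
        p = season_weather[k].precip
        i = sum(ev.depth for ev in irr_by_date.get(date, []))
        wet_depths.append(p + i)
        precip_depths.append(p)
    interval_wet = mean_wetting_interval(wet_depths, l_ini)
    interval_precip = mean_wetting_interval(precip_depths, l_ini)
    kc_ini = kc_ini_adjust(
        float(np.mean(et0[ini_slice])), interval_wet, soil.texture_class,
        fw=fw, precip_interval=interval_precip,
    )
    mid_slice = slice(l_ini + l_dev, l_ini + l_dev + l_mid)
    late_slice = slice(l_ini + l_dev + l_mid, total_days)
    rh_mid = float(np.mean([_rh_min_of_day(d) for d in season_weather[mid_slice]]))
    rh_late = float(np.mean([_rh_min_of_day(d) for d in season_weather[late_slice]]))
    phen = build_phenology(crop, total_days, kc_ini=kc_ini,
                           rh_min_mid=rh_mid, rh_min_late=rh_late)

    # --- initial state
    taw0, raw0 = storage_capacities(soil, float(phen.zr[0]), crop.p_tab)
    dr0 = initial_depletion(moisture_class, taw0)
    dr0_rel = dr0 / taw0
    theta0 = soil.theta_fc - dr0 / (float(phen.zr[0]) * 1000.0)
    prev = DailyState(
        day_index=0, date=sowing - datetime.timedelta(days=1),
        dr=dr0, theta=theta0, zr=float(phen.zr[0]), taw=taw0, raw=raw0,
        kc=0.0, ks=1.0, et0=0.0, etc=0.0, eta=0.0, int_p=0.0, int_i=0.0,
        ro=0.0, dp=0.0, p=0.0, i=0.0, storage_added=0.0,
    )

    states: list[DailyState] = []
    for k in range(total_days):
        date = wanted[k]
        evs = irr_by_date.get(date, [])
        i_total = sum(ev.depth for ev in evs)
        i_above = sum(ev.depth for ev in evs if ev.above_canopy)
        forcing = DayForcing(
            day_index=k + 1, date=date, et0=float(et0[k]),
            precip=season_weather[k].precip, irrigation=i_total,
            irrigation_above=i_above, kc=float(phen.kc[k]),
            zr=float(phen.zr[k]), lai=float(phen.lai[k]),
        )
        prev = step_day(prev, forcing, soil, crop.p_tab, dr0_rel, options)
        states.append(prev)

    return SeasonResult(states=states, phenology=phen, dr0=dr0, taw0=taw0,
                        soil=soil, crop=crop)
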