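"""Season aggregation: irrigation requirement, green/blue water footprints,
and a small evaluation harness for comparing simulated against observed
seasonal evapotranspiration.

The net irrigation requirement is the seasonal potential crop water use not
met by net precipitation.  The blue water footprint charges to irrigation
water the smaller of the requirement and the irrigation that actually
infiltrated (net of interception, runoff and deep percolation attributed to
it); the green footprint is the remainder of total consumptive use.  One mm
over one hectare is 10 m3, so footprints in m3 kg-1 are (mm depth) * 10 /
(yield in kg ha-1).  Water stored in the harvested product (order 0.1% of
the footprint) and conveyance losses are not accounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def attribute_losses(trace: pd.DataFrame) -> tuple[float, float]:
    """Season totals of net precipitation and net irrigation (mm).

    Daily runoff and deep percolation are attributed to rain versus
    irrigation in proportion to their same-day contributions to the water
    that reached the soil surface (after interception), mirroring the
    proportional attribution of interception itself.
    """
    p_surf = (trace["p"] - trace["int_p"]).to_numpy(dtype=float)
    i_surf = (trace["i"] - trace["int_i"]).to_numpy(dtype=float)
    tot = p_surf + i_surf
    with np.errstate(invalid="ignore", divide="ignore"):
        share_i = np.where(tot > 0, i_surf / np.where(tot > 0, tot, 1.0), 0.0)
    ro = trace["ro"].to_numpy(dtype=float)
    dp = trace["dp"].to_numpy(dtype=float)
    ro_i = ro * share_i
    dp_i = dp * share_i
    inet = float(trace["i"].sum() - trace["int_i"].sum() - ro_i.sum() - dp_i.sum())
    pnet = float(trace["p"].sum() - trace["int_p"].sum() - (ro - ro_i).sum() - (dp - dp_i).sum())
    return pnet, inet


def irrigation_requirement(trace: pd.DataFrame, literal_pnet: bool = False) -> float:
    """Seasonal irrigation requirement Ireq (mm), clamped at zero.

    Ireq = sum(ET0 * Kc) - Pnet.  By default Pnet is net precipitation
    only (the standard net irrigation requirement).  With
    ``literal_pnet=True`` net irrigation is also subtracted, i.e. the
    requirement still unmet after the applied irrigation.
    """
    pnet, inet = attribute_losses(trace)
    etc_sum = float(trace["etc"].sum())
    pnet_term = pnet + inet if literal_pnet else pnet
    return max(etc_sum - pnet_term, 0.0)


def water_footprints(
    sum_eta: float,
    ireq: float,
    inet: float,
    yield_kg_ha: float,
) -> tuple[float, float, float]:
    """Blue, green and total water footprints (m3 kg-1).

    WFPblue = min(Ireq, Inet) * 10 / Y, clamped at zero (footprints are
    non-negative by definition); WFPtotal = sum(ETa) * 10 / Y; WFPgreen is
    the difference, so blue + green = total holds identically.
    """
    if yield_kg_ha <= 0:
        raise ValueError(f"yield {yield_kg_ha} kg/ha must be positive")
    wfp_blue = max(min(ireq, inet), 0.0) * 10.0 / yield_kg_ha
    wfp_total = sum_eta * 10.0 / yield_kg_ha
    return wfp_blue, wfp_total - wfp_blue, wfp_total


@dataclass(frozen=True)
class SeasonSummary:
    """Season totals (mm) and the per-yield water footprints (m3 kg-1)."""

    sum_eta: float
    sum_etc: float
    sum_et0: float
    sum_p: float
    sum_i: float
    sum_ro: float
    sum_dp: float
    sum_interception: float
    pnet: float
    inet: float
    ireq: float
    yield_kg_ha: float
    wfp_blue: float
    wfp_green: float
    wfp_total: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def report(self) -> str:
        """Human-readable season report."""
        lines = [
            "Season water balance (mm)",
            f"  reference ET (ET0)        {self.sum_et0:9.1f}",
            f"  potential crop ET (ETc)   {self.sum_etc:9.1f}",
            f"  actual crop ET (ETa)      {self.sum_eta:9.1f}",
            f"  precipitation             {self.sum_p:9.1f}   net {self.pnet:9.1f}",
            f"  irrigation applied        {self.sum_i:9.1f}   net {self.inet:9.1f}",
            f"  interception loss         {self.sum_interception:9.1f}",
            f"  surface runoff            {self.sum_ro:9.1f}",
            f"  deep percolation          {self.sum_dp:9.1f}",
            f"  irrigation requirement    {self.ireq:9.1f}",
            "Water footprints",
            f"  yield                     {self.yield_kg_ha:9.0f} kg/ha",
            f"  blue WFP   {self.wfp_blue:8.4f} m3/kg  ({self.wfp_blue * 1000:8.1f} l/kg)",
            f"  green WFP  {self.wfp_green:8.4f} m3/kg  ({self.wfp_green * 1000:8.1f} l/kg)",
            f"  total WFP  {self.wfp_total:8.4f} m3/kg  ({self.wfp_total * 1000:8.1f} l/kg)",
        ]
        return "\n".join(lines)


def summarize_season(
    trace: pd.DataFrame,
    yield_kg_ha: float,
    literal_pnet: bool = False,
) -> SeasonSummary:
    """Aggregate a daily trace into the season summary and footprints."""
    pnet, inet = attribute_losses(trace)
    ireq = irrigation_requirement(trace, literal_pnet=literal_pnet)
    sum_eta = float(trace["eta"].sum())
    wfp_blue, wfp_green, wfp_total = water_footprints(sum_eta, ireq, inet, yield_kg_ha)
    return SeasonSummary(
        sum_eta=sum_eta,
        sum_etc=float(trace["etc"].sum()),
        sum_et0=float(trace["et0"].sum()),
        sum_p=float(trace["p"].sum()),
        sum_i=float(trace["i"].sum()),
        sum_ro=float(trace["ro"].sum()),
        sum_dp=float(trace["dp"].sum()),
        sum_interception=float(trace["int_p"].sum() + trace["int_i"].sum()),
        pnet=pnet,
        inet=inet,
        ireq=ireq,
        yield_kg_ha=yield_kg_ha,
        wfp_blue=wfp_blue,
        wfp_green=wfp_green,
        wfp_total=wfp_total,
    )


@dataclass(frozen=True)
class EvaluationMetrics:
    """Goodness-of-fit of simulated vs observed values."""

    rmse: float
    r_squared: float
    median_relative_error: float
    iqr_relative_error: tuple[float, float]


def evaluation_metrics(simulated, observed) -> EvaluationMetrics:
    """RMSE, R2 (ordinary least squares of simulated on observed), and the
    median and interquartile range of the relative error (sim - obs)/obs.

    Intended for comparing seasonal ETa or footprints against field
    observations from published trials.
    """
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError(f"length mismatch: {sim.shape} vs {obs.shape}")
    if sim.size < 2:
        raise ValueError("need at least two pairs")
    rmse = float(np.sqrt(np.mean((sim - obs) ** 2)))
    if np.allclose(sim, obs):
        r2 = 1.0
    else:
        res = stats.linregress(obs, sim)
        r2 = float(res.rvalue ** 2)
    rel = (sim - obs) / obs
    q25, q75 = np.percentile(rel, [25, 75])
    return EvaluationMetrics(
        rmse=rmse,
        r_squared=r2,
        median_relative_error=float(np.median(rel)),
        iqr_relative_error=(float(q25), float(q75)),
    )
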