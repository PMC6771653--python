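# Methods

## Model structure and assumptions

`cropwater` simulates one growing season at daily resolution. The state is
root-zone depletion Dr (mm below field capacity); everything else — water
content θ, stress coefficient Ks, actual evapotranspiration ETa — derives
from it. The governing assumptions are those of the single-crop-coefficient
family of models:

- The field is horizontally uniform; one bucket represents the root zone.
- Capillary rise and lateral flow are zero, so the model is valid only
  where groundwater is deep and fields are level.
- All water in excess of field capacity drains out of the root zone the
  same day (no perched layers, no impeded drainage).
- Crop development follows the calendar (stage lengths scaled to the
  user's growing period), not thermal time, and yield is an input, not an
  output: there is no feedback from water stress to the yield used in the
  footprint denominators.
- Nutrient, salinity and temperature stresses are not represented; Ks
  captures water stress only.

## Daily order of operations

Within one day the balance applies, in order: (1) root-zone deepening, with
newly accessed storage entering at the season-initial relative depletion
(subsoil untouched by surface fluxes is assumed to retain its initial
status); (2) canopy interception of rain plus above-canopy irrigation;
(3) surface runoff computed from the water reaching the soil, using the
previous day's soil wetness (pre-event moisture — the within-day ordering is
not otherwise constrained); (4) infiltration; (5) same-day deep percolation
of any excess below zero depletion; (6) stress evaluation and
evapotranspiration, with ETa additionally capped by the remaining store
(TAW − Dr); (7) θ recomputed from the closing depletion. Computing Ks after
inflows but before ET follows the common irrigation-scheduling convention.

This ordering makes the seasonal budget close identically:
Σ(P+I) − Σ(ETa+RO+DP+Int) − [Dr(0) + root-growth additions − Dr(end)] = 0
up to floating-point rounding; the test suite verifies closure to 1e-6 mm
over random seasons and typically observes ~1e-13 mm.

## Parameters that matter

| Parameter | Units | Default | Notes |
|---|---|---|---|
| u₂ (wind) | m s⁻¹ | 2 | fixed global average; local wind is rarely representative, so the Kc wind correction vanishes identically |
| albedo | – | 0.23 | grass reference surface |
| a (interception capacity) | mm d⁻¹ per LAI | 0.25 | canopy storage coefficient |
| b (soil cover) | – | LAI/3, capped at 1 | cover fraction cannot exceed full cover |
| β (runoff exponent) | – | 1 | RO = Ptot·((θ−θWP)/(θSAT−θWP))^β; exposed because alternative readings of the soil-moisture runoff scaling exist |
| p (depletion fraction) | – | crop table value, adjusted p + 0.04·(5 − ETc), clamped [0.1, 0.8] | adjustment on by default (`adjust_depletion`) |
| TEW/REW | mm | coarse (6, 2), medium (9, 4), fine (11, 5) | two-stage surface evaporation limits by texture group, used only for the initial Kc |
| k_Rs (radiation coefficient) | °C⁻⁰·⁵ | 0.16 (interior), 0.19 coastal | only used when solar radiation is missing |
| fw (wetted fraction) | – | drip 0.35, furrow 0.5, others 1.0 | method property |
| density_factor | – | 1.0 | bulk-density scaling of the pedotransfer porosity step; 1.0 returns the plain regression values |

Crop defaults (`data/crops.csv`: wheat, maize, potato, perennial grass) are
representative single-Kc table values — Kc triplets, stage-length fractions,
rooting depths, depletion fractions, heights and maximum LAI. They are
deliberately exposed as a plain-text table and per-run overrides, because
locally calibrated values always beat generic ones.

## Design choices where the design was open

- **Runoff functional form.** The relative-wetness power law was chosen for
  dimensional consistency and its correct limits (nothing at wilting point,
  everything at saturation). β is a run option so users can reproduce other
  readings of soil-moisture-scaled runoff.
- **Irrigation requirement.** Two definitions of net precipitation
  circulate: precipitation-only (the standard net irrigation requirement)
  and precipitation-plus-net-irrigation. The first is the default; the
  second is available as `literal_pnet=True`. They coincide for rain-fed
  fields.
- **Wetting events for the initial Kc.** A day wets the surface when at
  least 2 mm arrive. The wetted fraction of the surface counts rain plus
  all irrigation (every method wets its own fraction — that is exactly what
  fw encodes); the remaining (1 − fw) of the surface counts rain-only
  events. The mean inter-event interval drives the two-stage evaporation
  estimate; with fewer than two events the interval defaults to the stage
  length (a dry surface).
- **ea from humidity.** With minimum humidity available,
  ea = es(Tmax)·RHmin/100 (RHmin occurs near the daily temperature
  maximum); otherwise ea = RHmean/100·es. Both routes are exposed because
  reanalysis and station data differ in which humidity variable they
  provide.
- **Kc climate correction** applies to the mid-season value always and to
  the end value only when the tabulated Kc_end ≥ 0.45 (crops harvested
  green; crops left to dry are insensitive to air humidity). RHmin is
  clamped to the correction's 20–80 % validity range.
- **Root-growth carry.** Newly rooted soil enters at the season-initial
  relative depletion rather than at field capacity or at the current
  root-zone status — the subsoil has neither been wetted nor dried by the
  surface fluxes simulated so far.

## Numerical details

- ET₀ is clamped at ≥ 0 (condensation days count as zero demand); the
  relative shortwave ratio Rs/Rso is clamped to [0.25, 1], with a logged
  warning when measured Rs exceeds the clear-sky value; polar night
  (Ra = 0) is handled by treating the longwave term as clear-sky.
- Stage rescaling rounds each stage and absorbs the residual in the longest
  stage, so the four lengths always sum exactly to the season length and
  each stage keeps at least one day.
- The initial-Kc closed form is the exact integral of the two-stage
  evaporation process; the test suite verifies it against a brute-force
  fine-step integration.
- Irrigation events are spaced evenly (rounded to whole days) from the
  first to the last application date inclusive; a single event falls on the
  start date. Equal depths per event.
- Degenerate inputs: a one-day initial stage pins LAI at 0.1; a season
  shorter than 4 days, an unknown crop, weather gaps, events outside the
  season, and non-finite forcing all raise descriptive errors.

## Synthetic weather: what it does and does not emulate

The generator produces a sinusoidal annual temperature cycle with AR(1)
noise, a two-state wet/dry occurrence chain with exponential wet-day depths
(stationary wet-day frequency equals the spec value; persistence adds
realistic clustering), radiation as a clear-sky fraction reduced on wet
days, and humidity anti-correlated with the temperature anomaly and raised
on wet days. It does **not** emulate heat waves or frost events beyond AR
noise, seasonal precipitation regimes (monsoons), multi-day storm totals
with realistic extremes, or covariance structures taken from reanalysis.
Passing tests therefore demonstrate internal consistency and correct limit
behaviour of the balance under plausible forcing — not predictive accuracy
against field observations, which requires site data through the weather
CSV interface and the evaluation harness.

## Problem sizes used in the checks

The bundled scenarios are 120–150-day seasons. The acceptance script runs
365 random days for the reference-ET equivalence, 100 random seasons
(80–180 days each) for mass-balance closure, one stress-free and one
drought season of 130 days, and the four fixtures; the whole script
completes in a few seconds.

## Known limitations

- Soil evaporation outside the initial stage is folded into Kc (single-
  coefficient approach); no separate evaporation layer is tracked.
- The pedotransfer regressions were calibrated for topsoils and organic
  matter ≤ 8 %, but are applied over the full rooting depth; direct
  hydraulic measurements should be supplied where available.
- Runoff ignores rainfall intensity (daily totals only) and infiltration
  excess; it is purely saturation-scaled.
- The blue/green split attributes same-day losses proportionally; no
  carry-over attribution across days is attempted.
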