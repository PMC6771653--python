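"""Soil hydraulic limits from composition, and root-zone storage capacities.

Field capacity, permanent wilting point and saturation are estimated from
sand, clay and organic-matter content with the Saxton & Rawls (2006)
moisture-regression pedotransfer functions (1500 kPa and 33 kPa retention,
the SAT-33 kPa slope, and the porosity step, with an optional bulk-density
adjustment factor).  The regressions were calibrated for topsoils; they are
applied here over the full rooting depth, and an organic-matter content
above 8% is outside the calibration range and triggers a warning.

Direct hydraulic overrides are supported so local measurements can replace
the pedotransfer estimates whenever they are available.
"""

from __future__ import annotations

import logging
from enum import Enum
from typing import Optional

from pydantic import BaseModel, model_validator

logger = logging.getLogger(__name__)


class TextureClass(str, Enum):
    """Coarse/medium/fine grouping of the USDA texture triangle, used for
    the soil-evaporation parameters of the initial-stage crop coefficient."""

    COARSE = "coarse"
    MEDIUM = "medium"
    FINE = "fine"


class SoilComposition(BaseModel):
    """Mass fractions (0-1) of sand, clay and organic matter; silt is the
    remainder of the mineral fraction."""

    sand_frac: float
    clay_frac: float
    om_frac: float = 0.025

    @model_validator(mode="after")
    def _check(self) -> "SoilComposition":
        for name in ("sand_frac", "clay_frac", "om_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.sand_frac + self.clay_frac > 1.0:
            raise ValueError(
                f"sand_frac + clay_frac = {self.sand_frac + self.clay_frac:.3f} exceeds 1"
            )
        if self.om_frac > 0.08:
            logger.warning(
                "organic matter fraction %.3f exceeds the 0.08 pedotransfer calibration range",
                self.om_frac,
            )
        return self


class SoilHydraulics(BaseModel):
    """Volumetric water contents (m3 m-3) bounding the water balance:
    permanent wilting point < field capacity < saturation."""

    theta_wp: float
    theta_fc: float
    theta_sat: float
    texture_class: TextureClass = TextureClass.MEDIUM

    @model_validator(mode="after")
    def _check(self) -> "SoilHydraulics":
        if not (0.0 < self.theta_wp < self.theta_fc < self.theta_sat < 1.0):
            raise ValueError(
                "hydraulic ordering violated: need 0 < theta_wp < theta_fc < theta_sat < 1, got "
                f"({self.theta_wp:.3f}, {self.theta_fc:.3f}, {self.theta_sat:.3f})"
            )
        return self

    @property
    def available_water_capacity(self) -> float:
        """theta_fc - theta_wp (m3 m-3)."""
        return self.theta_fc - self.theta_wp


def texture_class_of(comp: SoilComposition) -> TextureClass:
    """Collapse composition to coarse (sand >= 60%), fine (clay >= 35%)
    or medium, matching the grouping of soil-evaporation parameters."""
    if comp.sand_frac >= 0.60:
        return TextureClass.COARSE
    if comp.clay_frac >= 0.35:
        return TextureClass.FINE
    return TextureClass.MEDIUM


def pedotransfer(comp: SoilComposition, density_factor: float = 1.0) -> SoilHydraulics:
    """Saxton-Rawls (2006) moisture regressions.

    ``S`` and ``C`` enter as decimal fractions and organic matter as percent
    by weight.  ``density_factor`` scales the normal-density bulk density
    (compaction > 1, loosening < 1); at 1.0 the plain regression values are
    returned.

    Returns wilting point (1500 kPa), field capacity (33 kPa) and
    saturation, plus the coarse/medium/fine texture class.
    """
    s = comp.sand_frac
    c = comp.clay_frac
    om = comp.om_frac * 100.0  # regressions use percent by weight

    t1500 = (
        -0.024 * s + 0.487 * c + 0.006 * om
        + 0.005 * s * om - 0.013 * c * om + 0.068 * s * c + 0.031
    )
    theta_wp = t1500 + (0.14 * t1500 - 0.02)

    t33 = (
        -0.251 * s + 0.195 * c + 0.011 * om
        + 0.006 * s * om - 0.027 * c * om + 0.452 * s * c + 0.299
    )
    theta_fc = t33 + (1.283 * t33 ** 2 - 0.374 * t33 - 0.015)

    ts33 = (
        0.278 * s + 0.034 * c + 0.022 * om
        - 0.018 * s * om - 0.027 * c * om - 0.584 * s * c + 0.078
    )
    theta_s33 = ts33 + (0.636 * ts33 - 0.107)

    theta_sat = theta_fc + theta_s33 - 0.097 * s + 0.043

    if density_factor != 1.0:
        # density adjustment: scale normal bulk density, recompute porosity
        # and shift field capacity by 20% of the porosity change
        rho_n = (1.0 - theta_sat) * 2.65
        rho_df = rho_n * density_factor
        theta_sat_df = 1.0 - rho_df / 2.65
        theta_fc = theta_fc - 0.2 * (theta_sat - theta_sat_df)
        theta_sat = theta_sat_df

    return SoilHydraulics(
        theta_wp=theta_wp,
        theta_fc=theta_fc,
        theta_sat=theta_sat,
        texture_class=texture_class_of(comp),
    )


def storage_capacities(soil: SoilHydraulics, zr: float, p_depletion: float) -> tuple[float, float]:
    """Total and readily available water of the root zone (mm).

    TAW = (theta_fc - theta_wp) * Zr * 1000 is the full storage between
    field capacity and wilting point over rooting depth ``zr`` (m); RAW is
    the depletion fraction ``p_depletion`` of TAW within which the crop
    suffers no water stress.
    """
    if zr <= 0:
        raise ValueError(f"rooting depth zr={zr} must be positive")
    if not (0.0 < p_depletion < 1.0):
        raise ValueError(f"p_depletion={p_depletion} outside (0, 1)")
    taw = soil.available_water_capacity * zr * 1000.0
    return taw, p_depletion * taw


def adjusted_depletion_fraction(p_tab: float, etc: float) -> float:
    """Depletion fraction adjusted for daily atmospheric demand.

    p = p_tab + 0.04 (5 - ETc), clamped to [0.1, 0.8]: drier, higher-demand
    days stress the crop at smaller depletions.
    """
    return min(max(p_tab + 0.04 * (5.0 - etc), 0.1), 0.8)
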