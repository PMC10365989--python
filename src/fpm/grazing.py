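"""Grazing-land accounting from a pasture/NPP overlay.

Grazing land use is expressed as a hypothetical area: the grass actually
eaten in a country divided by the productivity of its potential grazing
land.  Productivity is the pasture-area-weighted mean of usable aboveground
net primary production (at most ``npp_usable_fraction``, default 75%, of
ANPP is assumed consumable by livestock).  Because only the grazed-biomass /
productivity ratio matters, the same footprint arises in very different real
grazing situations (extensive grazing over a large area, or intensive
grazing of a small one); within a fixed grid, more intake always means more
footprint.  Where productivity is very low the footprint is capped at
``land_cap_fraction`` (default 80%) of the country's land area.  Grazing
green water is the grazed area times the country's actual-evapotranspiration
rate; grazing has no blue component.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import GrazingError, ValidationError

logger = logging.getLogger(__name__)

HA_PER_KM2 = 100.0


def grazing_productivity(grid: pd.DataFrame, usable_fraction: float) -> pd.Series:
    """Country grazing-land productivity (t usable biomass per km2 pasture).

    ``p_c = sum(usable_fraction * anpp * pasture_area) / sum(pasture_area)``
    over the country's cells; countries with zero pasture area get NaN.

    ``grid`` columns: ``cell_id, country, cell_area_km2, pasture_fraction,
    anpp_t_per_km2``.
    """
    if not (0.0 < usable_fraction <= 1.0):
        raise ValidationError(f"usable_fraction must lie in (0, 1], got {usable_fraction}")
    g = grid.copy()
    if (g["pasture_fraction"] < 0).any() or (g["pasture_fraction"] > 1).any():
        raise ValidationError("pasture_fraction must lie in [0, 1]")
    if (g["anpp_t_per_km2"] < 0).any() or (g["cell_area_km2"] < 0).any():
        raise ValidationError("cell areas and ANPP must be non-negative")
    g["pasture_area"] = g["cell_area_km2"] * g["pasture_fraction"]
    g["usable"] = usable_fraction * g["anpp_t_per_km2"] * g["pasture_area"]
    sums = g.groupby("country")[["usable", "pasture_area"]].sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        p = sums["usable"] / sums["pasture_area"]
    p[sums["pasture_area"] <= 0] = np.nan
    p.name = "productivity_t_per_km2"
    return p


def grazable_biomass(area_km2: float, productivity_t_per_km2: float) -> float:
    """Total grazable biomass (t) on ``area_km2`` of grazing land."""
    if area_km2 < 0 or productivity_t_per_km2 < 0:
        raise ValidationError("area and productivity must be non-negative")
    return area_km2 * productivity_t_per_km2


def grazing_lf(
    intake_t: float,
    productivity_t_per_km2: float,
    land_area_km2: float,
    cap_fraction: float,
) -> tuple[float, bool]:
    """Grazing land footprint (km2) with the land-area cap.

    ``lf = min(intake / productivity, cap_fraction * land_area)``; the flag
    reports whether the cap binds.  Zero intake yields zero footprint even
    where productivity is undefined.
    """
    if intake_t < 0:
        raise ValidationError("intake must be non-negative")
    if intake_t == 0:
        return 0.0, False
    if not (productivity_t_per_km2 > 0) or math.isnan(productivity_t_per_km2):
        raise GrazingError(
            f"positive grass intake {intake_t} t with undefined grazing productivity"
        )
    uncapped = intake_t / productivity_t_per_km2
    cap = cap_fraction * land_area_km2
    if uncapped > cap:
        return cap, True
    return uncapped, False


def grazing_intensity(intake_t: float, grazable_biomass_t: float) -> float:
    """Grass eaten as a percentage of total grazable biomass."""
    if intake_t < 0:
        raise ValidationError("intake must be non-negative")
    if intake_t == 0:
        return 0.0
    if grazable_biomass_t <= 0:
        raise GrazingError("positive intake with zero grazable biomass")
    return 100.0 * intake_t / grazable_biomass_t


def grazing_green_wf(lf_km2: float, et_rate_m3_per_ha: float) -> float:
    """Green water of grazing (m3): grazed area (ha) times ET rate.

    Grazing has no blue water component by definition.
    """
    if lf_km2 < 0 or et_rate_m3_per_ha < 0:
        raise ValidationError("footprint and ET rate must be non-negative")
    return lf_km2 * HA_PER_KM2 * et_rate_m3_per_ha


@dataclass
class GrazingAccount:
    """Full grazing account of one country."""

    country: str
    productivity_t_per_km2: float
    pasture_area_km2: float
    land_area_km2: float
    grazable_biomass_t: float
    intake_t: float
    lf_km2: float
    capped: bool
    intensity_pct: float
    green_wf_m3: float


def compute_grazing_accounts(
    grid: pd.DataFrame,
    intake: pd.DataFrame,
    et_rates: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Country-level grazing accounts from the grid, intake and ET tables.

    Grazable biomass uses the pasture area; the footprint cap uses the
    country's total cell area ("available land").  With
    ``config.grazing_wf_uses_cap`` (default) the green water footprint is
    computed from the capped area, keeping land and water accounting
    harmonized; otherwise from the uncapped intake/productivity area.

    Returns one row per country appearing in the grid or the intake table.
    """
    config = config or RunConfig()
    productivity = grazing_productivity(grid, config.npp_usable_fraction)
    g = grid.copy()
    g["pasture_area"] = g["cell_area_km2"] * g["pasture_fraction"]
    areas = g.groupby("country")[["cell_area_km2", "pasture_area"]].sum()
    intake_by_country = intake.groupby("country")["quantity_t"].sum()
    et_by_country = et_rates.set_index("country")["et_green_m3_per_ha"]
    countries = sorted(set(areas.index) | set(intake_by_country.index))
    rows = []
    for country in countries:
        p = float(productivity.get(country, np.nan))
        pasture = float(areas["pasture_area"].get(country, 0.0))
        land = float(areas["cell_area_km2"].get(country, 0.0))
        eaten = float(intake_by_country.get(country, 0.0))
        biomass = grazable_biomass(pasture, 0.0 if math.isnan(p) else p)
        if eaten > 0 and math.isnan(p):
            raise GrazingError(
                f"country {country!r} has grass intake {eaten} t but no pasture"
            )
        lf, capped = grazing_lf(eaten, p if not math.isnan(p) else 0.0, land,
                                config.land_cap_fraction)
        intensity = grazing_intensity(eaten, biomass) if biomass > 0 or eaten == 0 else np.nan
        if capped:
            logger.warning(
                "grazing LF of %s capped at %.1f%% of land area (intake %.6g t)",
                country, 100 * config.land_cap_fraction, eaten,
            )
        et = float(et_by_country.get(country, 0.0))
        if config.grazing_wf_uses_cap or not capped:
            wf_area = lf
        else:
            wf_area = eaten / p
        rows.append(
            GrazingAccount(
                country=country,
                productivity_t_per_km2=p,
                pasture_area_km2=pasture,
                land_area_km2=land,
                grazable_biomass_t=biomass,
                intake_t=eaten,
                lf_km2=lf,
                capped=capped,
                intensity_pct=intensity,
                green_wf_m3=grazing_green_wf(wf_area, et),
            ).__dict__
        )
    return pd.DataFrame(rows)
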