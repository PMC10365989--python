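"""Presentation-level aggregation: per-capita values, decompositions, comparison.

Stored footprints are full precision in base units (ha, m3); megahectares
and cubic kilometres appear only here, and rounding is half-up and applied
only at display.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import pandas as pd

from .errors import ComparisonError, MappingError, ReportingError
from .results import FootprintResult, WATER_COLOUR

HA_PER_MHA = 1e6
LITRES_PER_KM3 = 1e12

DECOMPOSE_AXES = ("food_class", "water_colour", "product_group", "origin_continent")


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding for display (matches printed tables)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def per_capita_area(total_mha: float, population: float) -> float:
    """Mha/yr -> ha per person per year (full precision; display rounds to 3 dp)."""
    if population <= 0:
        raise ReportingError(f"population must be positive, got {population}")
    return total_mha * HA_PER_MHA / population


def per_capita_water(total_km3: float, population: float, days: int = 365) -> float:
    """km3/yr -> litres per person per day (full precision; display rounds to int)."""
    if population <= 0:
        raise ReportingError(f"population must be positive, got {population}")
    if days not in (365, 366):
        raise ReportingError(f"days must be 365 or 366, got {days}")
    return total_km3 * LITRES_PER_KM3 / (population * days)


@dataclass
class Decomposition:
    """An aggregated footprint view with its marginals."""

    table: pd.DataFrame  # grouped sums along the requested axes (+ indicator)
    grand_total: float
    marginals: dict[str, pd.Series]
    domestic_share: float | None  # fraction of value with origin == consumer


def decompose(
    result: FootprintResult,
    axes: Sequence[str],
    region_map: pd.DataFrame | None = None,
    product_groups: pd.DataFrame | None = None,
) -> Decomposition:
    """Group-and-sum a footprint along presentation axes.

    Axes: ``food_class``, ``water_colour`` (green/blue, water rows only),
    ``product_group`` (via the user mapping table), ``origin_continent``
    (via the country->continent map).  The grand total over all rows is
    conserved except for the ``water_colour`` axis, which restricts to water
    indicators.
    """
    bad = set(axes) - set(DECOMPOSE_AXES)
    if bad:
        raise ReportingError(f"unknown decomposition axes {sorted(bad)}")
    frame = result.frame.copy()
    if "water_colour" in axes:
        frame = frame[frame["indicator"].isin(WATER_COLOUR)].copy()
        frame["water_colour"] = frame["indicator"].map(WATER_COLOUR)
    if "origin_continent" in axes:
        if region_map is None:
            raise MappingError("origin_continent axis requires a region map")
        mapping = region_map.set_index("country")["continent"]
        frame["origin_continent"] = frame["origin"].map(mapping)
        if frame["origin_continent"].isna().any():
            offenders = sorted(frame.loc[frame["origin_continent"].isna(), "origin"].unique())
            raise MappingError(f"origins without continent mapping: {offenders}")
    if "product_group" in axes:
        if product_groups is None:
            raise MappingError("product_group axis requires a product-group table")
        mapping = product_groups.set_index("commodity")["group"]
        frame["product_group"] = frame["product"].map(mapping)
        if frame["product_group"].isna().any():
            offenders = sorted(frame.loc[frame["product_group"].isna(), "product"].unique())
            raise MappingError(f"products without group mapping: {offenders}")
    keys = ["indicator"] + [a for a in axes if a != "water_colour"] + (
        ["water_colour"] if "water_colour" in axes else []
    )
    table = frame.groupby(keys, sort=True, as_index=False)["value"].sum()
    marginals = {
        axis: frame.groupby(axis)["value"].sum()
        for axis in axes
    }
    domestic = None
    if len(frame):
        domestic = float(
            frame.loc[frame["origin"] == frame["consumer"], "value"].sum()
            / frame["value"].sum()
        )
    return Decomposition(
        table=table,
        grand_total=float(frame["value"].sum()),
        marginals=marginals,
        domestic_share=domestic,
    )


def compare_models(results: Sequence[FootprintResult]) -> pd.DataFrame:
    """Side-by-side totals per indicator across model variants.

    Rows: (indicator, food_class) including an ``all`` food-class total;
    columns: one per variant plus ``min``, ``max`` and ``spread`` across
    variants.  All variants must report the same indicator set.
    """
    if not results:
        raise ComparisonError("no results to compare")
    indicator_sets = [frozenset(r.frame["indicator"].unique()) for r in results]
    if len(set(indicator_sets)) > 1:
        raise ComparisonError(
            f"mismatched indicator sets across variants: {sorted(set(indicator_sets), key=sorted)}"
        )
    frames = []
    for result in results:
        frame = result.frame.copy()
        totals = frame.groupby(["model_variant", "indicator", "food_class"])["value"].sum()
        alls = frame.groupby(["model_variant", "indicator"])["value"].sum()
        alls.index = pd.MultiIndex.from_tuples(
            [(v, i, "all") for v, i in alls.index],
            names=["model_variant", "indicator", "food_class"],
        )
        frames.append(pd.concat([totals, alls]))
    stacked = pd.concat(frames)
    wide = stacked.unstack("model_variant")
    wide["min"] = wide.min(axis=1)
    wide["max"] = wide.max(axis=1)
    wide["spread"] = wide["max"] - wide["min"]
    return wide.reset_index()
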