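"""End-to-end footprint runs: the physical-tracing and MRIO engines.

``phys_footprint`` follows the physical accounting route: convert traded
flows of derived products into primary-crop equivalents, resolve re-export
origins per commodity, subtract feed use from apparent consumption, embed
the feed and grazing footprints into livestock products, and convert
origin-resolved tonnes into land and water footprints with origin-country
intensities.

``mrio_footprint`` runs the same world through the supply--use/Leontief
route: the tables are linearized into a multi-regional coefficient system
and final demand pulls footprints through the inverse.

On worlds whose flows obey proportional mixing the two routes agree on
totals; their product resolution differs (tracing reports derived products
under their primary crop, the MRIO under their own name), which is exactly
the kind of classification difference multi-model comparisons surface.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .commodities import CommodityTree, embed_feed, to_primary_equivalents
from .config import RunConfig
from .errors import ValidationError
from .grazing import compute_grazing_accounts
from .io import WorldDataset
from .mrio import SupplyUseSystem, classify_food, leontief_footprint, sut_to_coefficients
from .results import FootprintResult
from .tracing import (
    attach_intensities,
    build_share_system,
    origin_resolved_consumption,
    trace_origins,
)
from .synthetic import GRASS

logger = logging.getLogger(__name__)


def _grazing_pool(dataset: WorldDataset, config: RunConfig) -> pd.DataFrame:
    """Per-country grazing footprints as feed-pool rows (origin = home country)."""
    if dataset.grass_intake is None or dataset.grassland_grid is None:
        return pd.DataFrame(columns=["country", "indicator", "origin", "value"])
    et = dataset.et_rates
    if et is None:
        et = pd.DataFrame({"country": [], "et_green_m3_per_ha": []})
    accounts = compute_grazing_accounts(
        dataset.grassland_grid, dataset.grass_intake, et, config
    )
    rows = []
    for row in accounts.itertuples(index=False):
        if row.lf_km2 > 0:
            rows.append(
                {"country": row.country, "indicator": "LF_grazing_ha",
                 "origin": row.country, "value": row.lf_km2 * 100.0}
            )
        if row.green_wf_m3 > 0:
            rows.append(
                {"country": row.country, "indicator": "WF_green_m3",
                 "origin": row.country, "value": row.green_wf_m3}
            )
    return pd.DataFrame(rows, columns=["country", "indicator", "origin", "value"])


def phys_footprint(
    dataset: WorldDataset, config: RunConfig | None = None
) -> FootprintResult:
    """Consumption footprints via physical trade tracing.

    Returns a footprint labelled ``PHYS-<allocation_mode>`` with food classes
    applied per ``config.food_scenario`` when the dataset carries a
    classification.
    """
    config = config or RunConfig()
    variant = f"PHYS-{config.allocation_mode}"
    livestock = (
        list(dataset.feed_weights["livestock_product"])
        if dataset.feed_weights is not None
        else []
    )
    commodities = sorted(set(dataset.production["commodity"]) - {GRASS})
    crop_like = [c for c in commodities if c not in livestock]
    tensor = dataset.trade_tensor(crop_like)
    if dataset.commodity_tree is not None and len(dataset.commodity_tree):
        tree = CommodityTree(dataset.commodity_tree)
        tensor = to_primary_equivalents(
            tensor,
            tree,
            config.allocation_mode,
            primaries=set(crop_like),
            missing=config.untracked_commodities,
            include_production=False,
        )
    yields = dataset.yields if dataset.yields is not None else pd.DataFrame(
        columns=["commodity", "country", "yield_t_per_ha"]
    )
    wf = dataset.wf_coefficients if dataset.wf_coefficients is not None else pd.DataFrame(
        columns=["commodity", "country", "green_m3_per_t", "blue_m3_per_t"]
    )
    feed_use = dataset.feed_use if dataset.feed_use is not None else pd.DataFrame(
        columns=["country", "feed_commodity", "quantity_t"]
    )
    feed_lookup = feed_use.groupby(["country", "feed_commodity"])["quantity_t"].sum()

    food_pieces: list[pd.DataFrame] = []
    feed_pieces: list[pd.DataFrame] = []
    for commodity in tensor.commodities:
        system = build_share_system(tensor, commodity, config.max_iterations)
        if system.supply.sum() <= 0:
            continue
        shares = trace_origins(system, tolerance=config.solve_tolerance,
                               max_iterations=config.max_iterations)
        consumption = origin_resolved_consumption(shares, system)
        if consumption.empty:
            continue
        totals = consumption.groupby("consumer")["tonnes"].sum()
        feed_fraction = {}
        for consumer, total in totals.items():
            feed = float(feed_lookup.get((consumer, commodity), 0.0))
            if feed > total + 1e-9 * max(total, 1.0):
                logger.warning(
                    "%s: feed use %.6g exceeds apparent consumption %.6g in %s; clipped",
                    commodity, feed, total, consumer,
                )
                feed = total
            feed_fraction[consumer] = feed / total if total > 0 else 0.0
        fraction = consumption["consumer"].map(feed_fraction).fillna(0.0)
        feed_part = consumption.assign(tonnes=consumption["tonnes"] * fraction)
        food_part = consumption.assign(tonnes=consumption["tonnes"] * (1.0 - fraction))
        food_pieces.append(food_part[food_part["tonnes"] > 0])
        feed_pieces.append(feed_part[feed_part["tonnes"] > 0])

    result = FootprintResult()
    if food_pieces:
        food = pd.concat(food_pieces, ignore_index=True)
        result = attach_intensities(food, yields, wf, model_variant=variant)

    # feed pool: crop footprints of feed tonnes, by origin, plus grazing
    pool_rows = []
    if feed_pieces:
        feed = pd.concat(feed_pieces, ignore_index=True)
        feed_fp = attach_intensities(feed, yields, wf, model_variant=variant)
        pool = feed_fp.frame.rename(columns={"consumer": "country"})
        pool_rows.append(pool[["country", "indicator", "origin", "value"]])
    grazing = _grazing_pool(dataset, config)
    if len(grazing):
        pool_rows.append(grazing)
    livestock_result = FootprintResult()
    if pool_rows and livestock:
        pool = pd.concat(pool_rows, ignore_index=True)
        pool = pool.groupby(["country", "indicator", "origin"], as_index=False)["value"].sum()
        outputs = dataset.production[dataset.production["commodity"].isin(livestock)]
        outputs = outputs.rename(columns={"commodity": "livestock_product"})[
            ["country", "livestock_product", "quantity_t"]
        ]
        weights = dataset.feed_weights.set_index("livestock_product")["weight"]
        attribution = embed_feed(pool, outputs, weights)
        # per-tonne intensities of each producing country's products
        intensity = attribution.merge(
            outputs, on=["country", "livestock_product"]
        )
        intensity["per_tonne"] = intensity["value"] / intensity["quantity_t"]
        lv_tensor = dataset.trade_tensor(livestock)
        lv_pieces = []
        for product in lv_tensor.commodities:
            system = build_share_system(lv_tensor, product, config.max_iterations)
            if system.supply.sum() <= 0:
                continue
            shares = trace_origins(system, tolerance=config.solve_tolerance,
                                   max_iterations=config.max_iterations)
            consumption = origin_resolved_consumption(shares, system)
            if consumption.empty:
                continue
            merged = consumption.rename(columns={"origin": "producer"}).merge(
                intensity.rename(
                    columns={"country": "producer", "livestock_product": "commodity",
                             "origin": "feed_origin"}
                )[["producer", "commodity", "indicator", "feed_origin", "per_tonne"]],
                on=["producer", "commodity"],
            )
            merged["value"] = merged["tonnes"] * merged["per_tonne"]
            lv_pieces.append(
                pd.DataFrame(
                    {
                        "model_variant": variant,
                        "consumer": merged["consumer"],
                        "product": merged["commodity"],
                        "origin": merged["feed_origin"],
                        "food_class": "unclassified",
                        "indicator": merged["indicator"],
                        "value": merged["value"],
                    }
                )
            )
        if lv_pieces:
            livestock_result = FootprintResult(pd.concat(lv_pieces, ignore_index=True))
    elif pool_rows and not livestock:
        logger.info("feed/grazing pool present but no livestock products; pool dropped")

    combined = FootprintResult.concat([result, livestock_result]).collapse()
    if dataset.food_classes is not None and len(combined):
        present = set(combined.frame["product"])
        classes = dataset.food_classes[dataset.food_classes["commodity"].isin(present)]
        missing = present - set(classes["commodity"])
        if missing:
            raise ValidationError(f"products without food class: {sorted(missing)}")
        combined = classify_food(combined, classes, config.food_scenario)
    return combined


def mrio_footprint(
    dataset: WorldDataset, config: RunConfig | None = None
) -> FootprintResult:
    """Consumption footprints via the supply--use/Leontief route.

    Returns a footprint labelled ``MRIO-<allocation_mode>-<food_scenario>``.
    """
    config = config or RunConfig()
    if dataset.supply is None or dataset.use is None or dataset.final_demand is None:
        raise ValidationError("dataset has no supply--use tables")
    extensions = dataset.extensions
    if extensions is None:
        extensions = pd.DataFrame(columns=["region", "industry", "indicator", "value"])
    prices = None
    if dataset.commodity_tree is not None and len(dataset.commodity_tree):
        prices = dataset.commodity_tree.set_index("child_commodity")["price_per_t"]
        prices = prices[~prices.index.duplicated()]
    trade = None
    if dataset.trade is not None and len(dataset.trade):
        trade = dataset.trade_tensor()
    sut = SupplyUseSystem(
        supply=dataset.supply,
        use=dataset.use,
        final_demand=dataset.final_demand,
        extensions=extensions,
        trade=trade,
        prices=prices,
    )
    variant = f"MRIO-{config.allocation_mode}-{config.food_scenario}"
    system = sut_to_coefficients(sut, config.allocation_mode)
    result = leontief_footprint(system, dataset.final_demand, model_variant=variant)
    if dataset.food_classes is not None and len(result):
        result = classify_food(result, dataset.food_classes, config.food_scenario)
    return result
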