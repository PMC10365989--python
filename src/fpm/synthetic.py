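"""Synthetic trade worlds with exactly attributable ground truth.

The generator builds small, internally consistent worlds that emulate the
statistical structure of global agricultural statistics — sparse bilateral
trade with re-export chains, multi-output processing, feed-mediated
livestock chains and heterogeneous yields — at a scale where every tonne can
be followed by hand.

Generative model
----------------
Countries are assigned to layers ``0 .. reexport_depth + 1`` and trade flows
only from lower to higher layers, so per-commodity trade is acyclic with
chain length at most ``reexport_depth + 1`` hops; an optional flag adds one
two-country cycle to exercise the linear-solve path (its shares are then
validated against the geometric-series oracle rather than path enumeration).
Every hop ships a fraction of the shipper's supply pool, mixed
proportionally over the pool's origins, so proportional-mixing tracing
recovers the generative attribution exactly.  Processing converts part of a
country's crop consumption into child products (traded one further hop);
livestock consume feed crops drawn from the local pool plus domestic grass.
Grass requirements are generated proportional to feed requirements so that
pool attribution by feed weights is exact.

Randomized quantities and their documented ranges (log-uniform unless
stated): crop production 1e3--1e6 t, yields 0.5--10 t/ha, green water
200--4000 m3/t, blue water 5--500 m3/t, land area 1e3--1e5 km2, cell ANPP
63--630 t/km2, ET 1000--6000 m3/ha (uniform), prices 200--2000 per t
(by-products 50--630), export fractions uniform 0.1--0.6 per hop.  All
draws come from one seeded generator; identical parameters and seed give
byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import ParameterError
from .io import WorldDataset
from .results import FootprintResult
from .tracing import TradeTensor

MAX_COUNTRIES = 50
MAX_COMMODITIES = 60
GRASS = "GRASS"


@dataclass(frozen=True)
class WorldParams:
    """Size and connectivity of a synthetic world."""

    n_countries: int = 8
    n_crops: int = 5
    n_livestock: int = 2
    n_processed: int = 2
    trade_density: float = 0.35
    reexport_depth: int = 2
    seed: int = 0
    add_cycle: bool = False

    def __post_init__(self) -> None:
        if not (2 <= self.n_countries <= MAX_COUNTRIES):
            raise ParameterError(f"n_countries must be in [2, {MAX_COUNTRIES}]")
        if self.n_crops < 1 or self.n_livestock < 0 or self.n_processed < 0:
            raise ParameterError("commodity counts out of range")
        n_commodities = self.n_crops + 2 * self.n_processed + self.n_livestock + 1
        if n_commodities > MAX_COMMODITIES:
            raise ParameterError(f"more than {MAX_COMMODITIES} commodities requested")
        if not (0.0 <= self.trade_density <= 1.0):
            raise ParameterError("trade_density must lie in [0, 1]")
        if self.reexport_depth < 0:
            raise ParameterError("reexport_depth must be >= 0")
        if self.reexport_depth > 0 and self.n_countries < 3:
            raise ParameterError("re-export chains require at least 3 countries")


@dataclass
class GroundTruth:
    """The generative attribution behind an emitted dataset.

    shipment_paths aggregates exactly to the emitted trade table; origin
    shares and footprints are computed by iterative flow propagation,
    independent of the tracing engine's direct solve.
    """

    shipment_paths: pd.DataFrame  # commodity, producer, route, consumer, tonnes
    true_origin_shares: dict[str, pd.DataFrame]  # commodity -> origin x consumer
    true_footprints: FootprintResult


def _log_uniform(rng: np.random.Generator, low: float, high: float, size=None):
    return np.exp(rng.uniform(np.log(low), np.log(high), size))


def _propagate_shares(p: np.ndarray, t: np.ndarray, tol: float = 1e-14,
                      max_terms: int = 100_000) -> tuple[np.ndarray, np.ndarray]:
    """Origin shares by geometric-series flow propagation (the oracle path)."""
    supply = p + t.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(supply[:, None] > 0, t / supply[:, None], 0.0)
    term = np.diag(p).astype(float)
    f = term.copy()
    for _ in range(max_terms):
        term = term @ b
        if np.abs(term).max() <= tol:
            break
        f += term
    with np.errstate(divide="ignore", invalid="ignore"):
        shares = np.where(supply[None, :] > 0, f / supply[None, :], 0.0)
    return shares, supply


def _enumerate_paths(
    commodity: str,
    countries: list[str],
    p: np.ndarray,
    t: np.ndarray,
    cutoff: float = 1e-9,
    max_hops: int = 64,
) -> Iterator[tuple[str, str, str, str, float]]:
    """Explicit shipment paths producer -> ... -> final consumer.

    On acyclic flow matrices the enumeration is exact; a tonnage cutoff
    guards the (optional) cyclic case.
    """
    supply = p + t.sum(axis=0)
    exports = t.sum(axis=1)
    n = len(p)
    edges: dict[int, list[int]] = {
        j: list(np.flatnonzero(t[j])) for j in range(n) if t[j].any()
    }

    def walk(route: list[int], amount: float):
        j = route[-1]
        if supply[j] <= 0:
            return
        retained = amount * (1.0 - exports[j] / supply[j])
        if retained > cutoff:
            yield route, retained
        if len(route) > max_hops:
            return
        for i in edges.get(j, ()):
            shipped = amount * t[j, i] / supply[j]
            if shipped > cutoff:
                yield from walk(route + [i], shipped)

    for m in np.flatnonzero(p > 0):
        for route, tonnes in walk([m], float(p[m])):
            yield (
                commodity,
                countries[m],
                ";".join(countries[i] for i in route),
                countries[route[-1]],
                tonnes,
            )


class _World:
    """Mutable scratch state while a world is being generated."""

    def __init__(self, params: WorldParams, config: RunConfig):
        self.params = params
        self.config = config
        self.rng = np.random.default_rng(params.seed)
        self.countries = [f"C{i:02d}" for i in range(params.n_countries)]
        self.crops = [f"CR{i:02d}" for i in range(params.n_crops)]
        self.processed = [f"PR{i:02d}" for i in range(params.n_processed)]
        self.livestock = [f"LV{i:02d}" for i in range(params.n_livestock)]
        self.production: dict[str, np.ndarray] = {}
        self.flows: dict[str, np.ndarray] = {}
        self.yields: dict[str, np.ndarray] = {}
        self.wf_green: dict[str, np.ndarray] = {}
        self.wf_blue: dict[str, np.ndarray] = {}
        self.tree_rows: list[dict] = []
        self.byproduct_of: dict[str, str] = {}


def generate_world(
    params: WorldParams, config: RunConfig | None = None
) -> tuple[WorldDataset, GroundTruth]:
    """Generate a consistent world and the ground truth behind it.

    The dataset satisfies node-level mass balance for every commodity and
    country (production + imports = exports + domestic use), its supply--use
    tables are assembled from the same flows as the trade tables, and the
    same parameters and seed always produce identical bytes.
    """
    config = config or RunConfig()
    w = _World(params, config)
    rng = w.rng
    n = params.n_countries
    depth = params.reexport_depth

    # -- geography -----------------------------------------------------------
    land_area = _log_uniform(rng, 1e3, 1e5, n)
    population = np.floor(_log_uniform(rng, 3e5, 3e7, n)).astype(int)
    continents = ["AMER", "EURA", "AFRI"][: (2 if n < 4 else 3)]
    continent = [continents[i % len(continents)] for i in range(n)]
    layers = rng.integers(0, depth + 2, n)

    # -- crops: production, intensities, layered trade DAG -------------------
    for k in w.crops:
        mask = rng.random(n) < 0.7
        if not mask.any():
            mask[rng.integers(0, n)] = True
        p = np.where(mask, _log_uniform(rng, 1e3, 1e6, n), 0.0)
        w.production[k] = p
        w.yields[k] = np.where(mask, _log_uniform(rng, 0.5, 10.0, n), np.nan)
        w.wf_green[k] = np.where(mask, _log_uniform(rng, 200.0, 4000.0, n), np.nan)
        w.wf_blue[k] = np.where(mask, _log_uniform(rng, 5.0, 500.0, n), np.nan)
    # every country must produce something (the production table is the registry)
    produces = np.sum([w.production[k] > 0 for k in w.crops], axis=0)
    for j in np.flatnonzero(produces == 0):
        k = w.crops[int(rng.integers(0, len(w.crops)))]
        w.production[k][j] = float(_log_uniform(rng, 1e3, 1e6))
        w.yields[k][j] = float(_log_uniform(rng, 0.5, 10.0))
        w.wf_green[k][j] = float(_log_uniform(rng, 200.0, 4000.0))
        w.wf_blue[k][j] = float(_log_uniform(rng, 5.0, 500.0))

    order = sorted(range(n), key=lambda j: (layers[j], j))
    for k in w.crops:
        t = np.zeros((n, n))
        supply = w.production[k].copy()
        for j in order:
            if supply[j] <= 0:
                continue
            candidates = [i for i in range(n) if layers[i] > layers[j]]
            if not candidates:
                continue
            chosen = [i for i in candidates if rng.random() < params.trade_density]
            if not chosen:
                continue
            fraction = rng.uniform(0.1, 0.6)
            weights = rng.dirichlet(np.ones(len(chosen)))
            for i, weight in zip(chosen, weights):
                shipped = supply[j] * fraction * weight
                t[j, i] += shipped
                supply[i] += shipped
        w.flows[k] = t
    if params.add_cycle and n >= 2:
        # one reciprocal flow on the first crop between the two best-supplied
        # countries: exercises the non-nilpotent (cyclic) solve path
        k = w.crops[0]
        supply = w.production[k] + w.flows[k].sum(axis=0) - w.flows[k].sum(axis=1)
        a_idx, b_idx = np.argsort(supply)[-2:]
        amount = 0.05 * min(supply[a_idx], supply[b_idx])
        if amount > 0:
            w.flows[k][a_idx, b_idx] += amount
            w.flows[k][b_idx, a_idx] += amount

    def consumption_of(k: str) -> np.ndarray:
        t = w.flows[k]
        return w.production[k] + t.sum(axis=0) - t.sum(axis=1)

    crop_consumption = {k: consumption_of(k) for k in w.crops}

    # Derived products (processed goods, livestock products) ship one hop to
    # top-layer sink countries only, and sinks raise no livestock.  Sinks
    # export nothing, so every engine attributes their imports identically —
    # the generated world obeys proportional mixing exactly rather than only
    # approximately.
    sinks = [i for i in range(n) if layers[i] == depth + 1]

    # -- processing chains ---------------------------------------------------
    processing_input: dict[str, np.ndarray] = {}  # process -> per-country parent tonnes
    process_parent: dict[str, str] = {}
    process_children: dict[str, list[tuple[str, float]]] = {}
    available = {k: crop_consumption[k].copy() for k in w.crops}
    for p_idx, child in enumerate(w.processed):
        parent = w.crops[p_idx % len(w.crops)]
        process = f"proc_{child}"
        rate_main = rng.uniform(0.15, 0.6)
        children = [(child, rate_main, float(_log_uniform(rng, 200.0, 2000.0)))]
        if rng.random() < 0.6:
            byproduct = f"BY{p_idx:02d}"
            rate_by = rng.uniform(0.1, 1.0 - rate_main)
            children.append((byproduct, rate_by, float(_log_uniform(rng, 50.0, 630.0))))
            w.byproduct_of[byproduct] = process
        for name, rate, price in children:
            w.tree_rows.append(
                {
                    "process": process,
                    "parent_commodity": parent,
                    "child_commodity": name,
                    "extraction_rate": rate,
                    "price_per_t": price,
                }
            )
        process_parent[process] = parent
        process_children[process] = [(name, rate) for name, rate, _ in children]
        q = np.zeros(n)
        for j in range(n):
            if available[parent][j] > 0 and rng.random() < 0.6:
                q[j] = rng.uniform(0.1, 0.4) * available[parent][j]
        processing_input[process] = q
        available[parent] = available[parent] - q
        for name, rate in process_children[process]:
            w.production[name] = q * rate
            t = np.zeros((n, n))
            for j in range(n):
                if w.production[name][j] <= 0 or j in sinks:
                    continue
                candidates = [i for i in sinks if i != j]
                chosen = [i for i in candidates if rng.random() < params.trade_density]
                if not chosen:
                    continue
                fraction = rng.uniform(0.1, 0.5)
                weights = rng.dirichlet(np.ones(len(chosen)))
                for i, weight in zip(chosen, weights):
                    t[j, i] += w.production[name][j] * fraction * weight
            w.flows[name] = t

    # -- livestock fed from local pools and domestic grass -------------------
    feed_intensity = {v: rng.uniform(1.0, 6.0) for v in w.livestock}
    grass_ratio = rng.uniform(0.3, 1.0)
    herd = np.zeros((len(w.livestock), n))
    for v_idx, v in enumerate(w.livestock):
        mask = (rng.random(n) < 0.6) & (layers != depth + 1)
        herd[v_idx] = np.where(mask, _log_uniform(rng, 1e2, 1e4, n), 0.0)
    feed_available = np.array([np.clip(available[k], 0.0, None) for k in w.crops])
    if len(w.livestock):
        demand = (
            np.array([[feed_intensity[v]] for v in w.livestock]) * herd
        ).sum(axis=0)
        budget = 0.7 * feed_available.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(demand > budget, np.where(demand > 0, budget / demand, 1.0), 1.0)
        herd *= scale[None, :]
    feed_by_crop_product: dict[tuple[str, str], np.ndarray] = {}
    total_feed = np.zeros(n)
    for v_idx, v in enumerate(w.livestock):
        f_v = feed_intensity[v] * herd[v_idx]
        total_feed += f_v
        with np.errstate(divide="ignore", invalid="ignore"):
            composition = np.where(
                feed_available.sum(axis=0) > 0,
                feed_available / feed_available.sum(axis=0)[None, :],
                0.0,
            )
        for k_idx, k in enumerate(w.crops):
            feed_by_crop_product[(k, v)] = f_v * composition[k_idx]
    grass_intake_by_product = {
        v: grass_ratio * feed_intensity[v] * herd[v_idx]
        for v_idx, v in enumerate(w.livestock)
    }
    grass_intake = np.sum(list(grass_intake_by_product.values()), axis=0) if w.livestock else np.zeros(n)
    for k_idx, k in enumerate(w.crops):
        used = np.sum([feed_by_crop_product[(k, v)] for v in w.livestock], axis=0) if w.livestock else 0.0
        available[k] = available[k] - used
    for v_idx, v in enumerate(w.livestock):
        w.production[v] = herd[v_idx]
        t = np.zeros((n, n))
        for j in range(n):
            if herd[v_idx, j] <= 0 or j in sinks:
                continue
            candidates = [i for i in sinks if i != j]
            chosen = [i for i in candidates if rng.random() < params.trade_density]
            if not chosen:
                continue
            fraction = rng.uniform(0.05, 0.4)
            weights = rng.dirichlet(np.ones(len(chosen)))
            for i, weight in zip(chosen, weights):
                t[j, i] += herd[v_idx, j] * fraction * weight
        w.flows[v] = t

    # -- grassland grid, ET, grazing extensions ------------------------------
    grid_rows = []
    pasture_area = np.zeros(n)
    usable_npp = np.zeros(n)
    for j in range(n):
        n_cells = int(rng.integers(1, 5))
        areas = land_area[j] * rng.dirichlet(np.ones(n_cells))
        for c_idx in range(n_cells):
            fraction = rng.uniform(0.05, 0.6)
            anpp = float(_log_uniform(rng, 63.0, 630.0))
            grid_rows.append(
                {
                    "cell_id": f"{w.countries[j]}_{c_idx}",
                    "country": w.countries[j],
                    "cell_area_km2": areas[c_idx],
                    "pasture_fraction": fraction,
                    "anpp_t_per_km2": anpp,
                }
            )
            pasture_area[j] += areas[c_idx] * fraction
            usable_npp[j] += config.npp_usable_fraction * anpp * areas[c_idx] * fraction
    productivity = np.where(pasture_area > 0, usable_npp / np.maximum(pasture_area, 1e-300), np.nan)
    et_rate = rng.uniform(1000.0, 6000.0, n)
    grazing_lf_km2 = np.zeros(n)
    grazing_wf_m3 = np.zeros(n)
    for j in range(n):
        if grass_intake[j] <= 0:
            continue
        uncapped = grass_intake[j] / productivity[j]
        grazing_lf_km2[j] = min(uncapped, config.land_cap_fraction * land_area[j])
        wf_area = grazing_lf_km2[j] if config.grazing_wf_uses_cap else uncapped
        grazing_wf_m3[j] = wf_area * 100.0 * et_rate[j]

    # -- emit tables ---------------------------------------------------------
    countries = w.countries

    def long_production() -> pd.DataFrame:
        rows = [
            {"commodity": k, "country": countries[j], "quantity_t": w.production[k][j]}
            for k in sorted(w.production)
            for j in range(n)
            if w.production[k][j] > 0
        ]
        return pd.DataFrame(rows, columns=["commodity", "country", "quantity_t"])

    def long_trade() -> pd.DataFrame:
        rows = [
            {
                "commodity": k,
                "origin": countries[j],
                "destination": countries[i],
                "quantity_t": w.flows[k][j, i],
            }
            for k in sorted(w.flows)
            for j in range(n)
            for i in range(n)
            if w.flows[k][j, i] > 0
        ]
        return pd.DataFrame(rows, columns=["commodity", "origin", "destination", "quantity_t"])

    yields_rows = [
        {"commodity": k, "country": countries[j], "yield_t_per_ha": w.yields[k][j]}
        for k in w.crops
        for j in range(n)
        if w.production[k][j] > 0
    ]
    wf_rows = [
        {
            "commodity": k,
            "country": countries[j],
            "green_m3_per_t": w.wf_green[k][j],
            "blue_m3_per_t": w.wf_blue[k][j],
        }
        for k in w.crops
        for j in range(n)
        if w.production[k][j] > 0
    ]
    feed_rows = []
    for k in w.crops:
        for j in range(n):
            total = sum(feed_by_crop_product[(k, v)][j] for v in w.livestock)
            if total > 0:
                feed_rows.append(
                    {"country": countries[j], "feed_commodity": k, "quantity_t": total}
                )
    weight_rows = [
        {"livestock_product": v, "weight": feed_intensity[v]} for v in w.livestock
    ]
    grass_rows = [
        {"country": countries[j], "quantity_t": grass_intake[j]}
        for j in range(n)
        if grass_intake[j] > 0
    ]

    # supply--use system assembled from the very same flows ------------------
    supply_rows, use_rows, ext_rows, demand_rows = [], [], [], []
    for j in range(n):
        c = countries[j]
        for k in w.crops:
            if w.production[k][j] > 0:
                industry = f"grow_{k}"
                supply_rows.append(
                    {"region": c, "industry": industry, "commodity": k, "value": w.production[k][j]}
                )
                ext_rows += [
                    {"region": c, "industry": industry, "indicator": "LF_crop_ha",
                     "value": w.production[k][j] / w.yields[k][j]},
                    {"region": c, "industry": industry, "indicator": "WF_green_m3",
                     "value": w.production[k][j] * w.wf_green[k][j]},
                    {"region": c, "industry": industry, "indicator": "WF_blue_m3",
                     "value": w.production[k][j] * w.wf_blue[k][j]},
                ]
        for process, q in processing_input.items():
            if q[j] > 0:
                use_rows.append(
                    {"region": c, "industry": process,
                     "commodity": process_parent[process], "value": q[j]}
                )
                for name, rate in process_children[process]:
                    supply_rows.append(
                        {"region": c, "industry": process, "commodity": name,
                         "value": q[j] * rate}
                    )
        if grass_intake[j] > 0:
            supply_rows.append(
                {"region": c, "industry": "graze", "commodity": GRASS, "value": grass_intake[j]}
            )
            ext_rows += [
                {"region": c, "industry": "graze", "indicator": "LF_grazing_ha",
                 "value": grazing_lf_km2[j] * 100.0},
                {"region": c, "industry": "graze", "indicator": "WF_green_m3",
                 "value": grazing_wf_m3[j]},
            ]
        for v_idx, v in enumerate(w.livestock):
            if herd[v_idx, j] <= 0:
                continue
            industry = f"raise_{v}"
            supply_rows.append(
                {"region": c, "industry": industry, "commodity": v, "value": herd[v_idx, j]}
            )
            for k in w.crops:
                amount = feed_by_crop_product[(k, v)][j]
                if amount > 0:
                    use_rows.append(
                        {"region": c, "industry": industry, "commodity": k, "value": amount}
                    )
            if grass_intake_by_product[v][j] > 0:
                use_rows.append(
                    {"region": c, "industry": industry, "commodity": GRASS,
                     "value": grass_intake_by_product[v][j]}
                )
        for k in w.crops:
            if available[k][j] > 1e-12:
                demand_rows.append(
                    {"region": c, "commodity": k, "category": "households",
                     "value": available[k][j]}
                )
        for name in list(w.processed) + list(w.byproduct_of) + list(w.livestock):
            if name not in w.production:
                continue
            t = w.flows.get(name, np.zeros((n, n)))
            cons = w.production[name][j] + t[:, j].sum() - t[j, :].sum()
            if cons > 1e-12:
                demand_rows.append(
                    {"region": c, "commodity": name, "category": "households", "value": cons}
                )

    class_rows = [{"commodity": k, "class": "food_certain"} for k in w.crops]
    for idx, name in enumerate(w.processed):
        class_rows.append(
            {"commodity": name, "class": "food_possible" if idx == 0 else "food_certain"}
        )
    class_rows += [{"commodity": b, "class": "nonfood"} for b in w.byproduct_of]
    class_rows += [{"commodity": v, "class": "food_certain"} for v in w.livestock]
    class_rows.append({"commodity": GRASS, "class": "nonfood"})
    group_rows = (
        [{"commodity": k, "group": "crops"} for k in w.crops]
        + [{"commodity": p, "group": "processed"} for p in w.processed]
        + [{"commodity": b, "group": "processed"} for b in w.byproduct_of]
        + [{"commodity": v, "group": "animal products"} for v in w.livestock]
        + [{"commodity": GRASS, "group": "grazing"}]
    )

    dataset = WorldDataset(
        production=long_production(),
        trade=long_trade(),
        commodity_tree=pd.DataFrame(
            w.tree_rows,
            columns=["process", "parent_commodity", "child_commodity",
                     "extraction_rate", "price_per_t"],
        ),
        yields=pd.DataFrame(yields_rows, columns=["commodity", "country", "yield_t_per_ha"]),
        wf_coefficients=pd.DataFrame(
            wf_rows, columns=["commodity", "country", "green_m3_per_t", "blue_m3_per_t"]
        ),
        feed_use=pd.DataFrame(feed_rows, columns=["country", "feed_commodity", "quantity_t"]),
        feed_weights=pd.DataFrame(weight_rows, columns=["livestock_product", "weight"]),
        grass_intake=pd.DataFrame(grass_rows, columns=["country", "quantity_t"]),
        grassland_grid=pd.DataFrame(grid_rows),
        et_rates=pd.DataFrame({"country": countries, "et_green_m3_per_ha": et_rate}),
        population=pd.DataFrame({"country": countries, "population": population}),
        supply=pd.DataFrame(supply_rows, columns=["region", "industry", "commodity", "value"]),
        use=pd.DataFrame(use_rows, columns=["region", "industry", "commodity", "value"]),
        final_demand=pd.DataFrame(
            demand_rows, columns=["region", "commodity", "category", "value"]
        ),
        extensions=pd.DataFrame(ext_rows, columns=["region", "industry", "indicator", "value"]),
        food_classes=pd.DataFrame(class_rows, columns=["commodity", "class"]),
        region_map=pd.DataFrame({"country": countries, "continent": continent}),
        commodity_groups=pd.DataFrame(group_rows, columns=["commodity", "group"]),
        provenance={"generator": "fpm.synthetic", "seed": params.seed},
    )

    truth = _ground_truth(w, dataset, config, available, feed_by_crop_product,
                          grazing_lf_km2, grazing_wf_m3, herd)
    return dataset, truth


def _ground_truth(
    w: _World,
    dataset: WorldDataset,
    config: RunConfig,
    final_crop: dict[str, np.ndarray],
    feed_by_crop_product: dict[tuple[str, str], np.ndarray],
    grazing_lf_km2: np.ndarray,
    grazing_wf_m3: np.ndarray,
    herd: np.ndarray,
) -> GroundTruth:
    """Assemble ground-truth shares, shipment paths and footprints.

    All origin resolution here uses iterative flow propagation (exact on the
    acyclic worlds, geometric-series truncation on cyclic ones) — never the
    tracing engine's direct linear solve.
    """
    countries = w.countries
    n = len(countries)
    path_rows = []
    shares: dict[str, pd.DataFrame] = {}
    for k in sorted(w.production):
        p = w.production[k]
        t = w.flows.get(k, np.zeros((n, n)))
        share, _ = _propagate_shares(p, t)
        shares[k] = pd.DataFrame(share, index=countries, columns=countries)
        path_rows.extend(_enumerate_paths(k, countries, p, t))
    paths = pd.DataFrame(
        path_rows, columns=["commodity", "producer", "route", "consumer", "tonnes"]
    )

    mode = config.allocation_mode
    from .commodities import CommodityTree

    tree = (
        CommodityTree(dataset.commodity_tree)
        if dataset.commodity_tree is not None and len(dataset.commodity_tree)
        else None
    )
    records: list[dict] = []
    class_map = dataset.food_classes.set_index("commodity")["class"].to_dict()
    food_set = {"min": {"food_certain"}, "max": {"food_certain", "food_possible"}}[
        config.food_scenario
    ]

    def food_class_of(commodity: str) -> str:
        return "food" if class_map.get(commodity) in food_set else "nonfood"

    def add(consumer, product, origin, indicator, value):
        if value > 0:
            records.append(
                {
                    "model_variant": f"PHYS-{mode}",
                    "consumer": consumer,
                    "product": product,
                    "origin": origin,
                    "food_class": food_class_of(product),
                    "indicator": indicator,
                    "value": value,
                }
            )

    # merged primary-equivalent flows per crop
    feed_pool: dict[tuple[str, str, str], float] = {}  # (country, indicator, origin)
    for k_idx, k in enumerate(w.crops):
        t_merged = w.flows[k].copy()
        if tree is not None:
            for derived in sorted(set(w.processed) | set(w.byproduct_of)):
                if derived not in w.flows:
                    continue
                primary, factor = tree.primary_equivalent_factor(derived, mode)
                if primary == k:
                    t_merged += w.flows[derived] * factor
        p = w.production[k]
        share, supply = _propagate_shares(p, t_merged)
        consumption = np.clip(supply - t_merged.sum(axis=1), 0.0, None)
        feed_total = np.zeros(n)
        for v in w.livestock:
            feed_total += feed_by_crop_product[(k, v)]
        food_tonnes = np.clip(consumption - feed_total, 0.0, None)
        for i in range(n):
            for m in np.flatnonzero(share[:, i] > 0):
                tonnes = food_tonnes[i] * share[m, i]
                add(countries[i], k, countries[m], "LF_crop_ha", tonnes / w.yields[k][m])
                add(countries[i], k, countries[m], "WF_green_m3", tonnes * w.wf_green[k][m])
                add(countries[i], k, countries[m], "WF_blue_m3", tonnes * w.wf_blue[k][m])
                feed_attr = feed_total[i] * share[m, i]
                if feed_attr > 0:
                    for indicator, intensity in (
                        ("LF_crop_ha", 1.0 / w.yields[k][m]),
                        ("WF_green_m3", w.wf_green[k][m]),
                        ("WF_blue_m3", w.wf_blue[k][m]),
                    ):
                        key = (countries[i], indicator, countries[m])
                        feed_pool[key] = feed_pool.get(key, 0.0) + feed_attr * intensity
    for j in range(n):
        if grazing_lf_km2[j] > 0:
            key = (countries[j], "LF_grazing_ha", countries[j])
            feed_pool[key] = feed_pool.get(key, 0.0) + grazing_lf_km2[j] * 100.0
            key = (countries[j], "WF_green_m3", countries[j])
            feed_pool[key] = feed_pool.get(key, 0.0) + grazing_wf_m3[j]

    # livestock: split pools by feed weights, follow product trade
    if len(w.livestock):
        weighted = np.zeros(n)
        for v_idx, v in enumerate(w.livestock):
            weighted += w.production[v] * (
                dataset.feed_weights.set_index("livestock_product")["weight"][v]
            )
        for v_idx, v in enumerate(w.livestock):
            weight = dataset.feed_weights.set_index("livestock_product")["weight"][v]
            share_v = np.where(weighted > 0, w.production[v] * weight / np.maximum(weighted, 1e-300), 0.0)
            share_lv, supply_lv = _propagate_shares(w.production[v], w.flows.get(v, np.zeros((n, n))))
            cons_lv = np.clip(supply_lv - w.flows.get(v, np.zeros((n, n))).sum(axis=1), 0.0, None)
            per_tonne: dict[int, dict[tuple[str, str], float]] = {}
            for (country, indicator, origin), value in feed_pool.items():
                j = countries.index(country)
                if w.production[v][j] > 0 and share_v[j] > 0:
                    per_tonne.setdefault(j, {})[(indicator, origin)] = (
                        value * share_v[j] / w.production[v][j]
                    )
            for i in range(n):
                for j in np.flatnonzero(share_lv[:, i] > 0):
                    tonnes = cons_lv[i] * share_lv[j, i]
                    for (indicator, origin), intensity in per_tonne.get(j, {}).items():
                        add(countries[i], v, origin, indicator, tonnes * intensity)

    footprints = FootprintResult(pd.DataFrame.from_records(records)) if records else FootprintResult()
    return GroundTruth(
        shipment_paths=paths,
        true_origin_shares=shares,
        true_footprints=footprints.collapse(),
    )


def perturb_world(
    dataset: WorldDataset, noise_level: float, seed: int
) -> WorldDataset:
    """Multiplicative lognormal noise on production and trade quantities.

    Emulates inconsistent reported statistics: balances are no longer exact,
    so reconciliation and clipping paths get exercised.  ``noise_level`` is
    the sigma of the log factor; zero is the identity.
    """
    if not (0.0 <= noise_level < 0.5):
        raise ParameterError("noise_level must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    new = replace(dataset)
    if noise_level > 0:
        production = dataset.production.copy()
        production["quantity_t"] = production["quantity_t"] * rng.lognormal(
            0.0, noise_level, len(production)
        )
        new.production = production
        if dataset.trade is not None:
            trade = dataset.trade.copy()
            trade["quantity_t"] = trade["quantity_t"] * rng.lognormal(
                0.0, noise_level, len(trade)
            )
            new.trade = trade
    return new
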