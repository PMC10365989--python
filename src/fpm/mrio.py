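"""Leontief demand-pull footprinting from multi-regional supply--use tables.

The engine linearizes an economy into nodes of two kinds:

* **producer nodes** — one per (region, industry, output commodity).  A
  multi-output industry is split into per-commodity virtual producers; its
  inputs and environmental extensions are allocated to the outputs by mass
  or value shares (the same rule the commodity tree uses for by-products).
* **pool nodes** — one per (region, commodity): the region's supply pool,
  fed by domestic producers and, where a bilateral trade tensor is given, by
  the exporting regions' pools in proportion to observed trade.  Pools give
  the system its multi-regional sourcing: every user of a commodity in a
  region draws on the same mix of domestic output and imports, and imports
  of re-exporters chain through their own pools, so origins resolve through
  the Leontief inverse exactly as in physical re-export tracing.

With technical coefficients A (input per unit output, column = consumer),
total output follows from final demand y as x = (I - A)^-1 y, and the
footprint of a demand bundle is the extension intensity e applied node-wise
to x, grouped by the producing node's region to give origins.  The tables
are unit-agnostic (physical tonnes or monetary units); units are a property
of the inputs, not of the algebra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import (
    ClassificationError,
    ConfigurationError,
    IndexingError,
    NonProductiveError,
    StructureError,
    ValidationError,
)
from .results import INDICATORS, FootprintResult
from .tracing import TradeTensor

logger = logging.getLogger(__name__)

#: beyond this node count the dense inverse is refused
DENSE_SIZE_CAP = 5_000


@dataclass
class SupplyUseSystem:
    """Supply, use, final-demand and extension tables, plus optional trade.

    Long-format frames:
      supply:        region, industry, commodity, value
      use:           region, industry, commodity, value
      final_demand:  region, commodity, category, value
      extensions:    region, industry, indicator, value
    ``trade`` supplies bilateral commodity flows used to build each pool's
    import mix; without it all sourcing is domestic.  ``prices`` (commodity
    -> price per unit) are needed only for value allocation of multi-output
    industries.
    """

    supply: pd.DataFrame
    use: pd.DataFrame
    final_demand: pd.DataFrame
    extensions: pd.DataFrame
    trade: TradeTensor | None = None
    prices: pd.Series | None = None

    def __post_init__(self) -> None:
        for name, frame, cols in (
            ("supply", self.supply, ["region", "industry", "commodity", "value"]),
            ("use", self.use, ["region", "industry", "commodity", "value"]),
            ("final_demand", self.final_demand, ["region", "commodity", "category", "value"]),
            ("extensions", self.extensions, ["region", "industry", "indicator", "value"]),
        ):
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                raise ValidationError(f"{name} table missing columns {missing}")
            if len(frame) and (frame["value"] < 0).any():
                raise ValidationError(f"{name} table has negative values")


@dataclass
class LeontiefSystem:
    """A solved-ready coefficient system with environmental extensions."""

    coefficients: np.ndarray  # A, column = consuming node
    extensions: dict[str, np.ndarray]  # indicator -> per-node extension per unit output
    node_region: np.ndarray  # region label per node
    node_kind: np.ndarray  # "producer" | "pool"
    node_commodity: np.ndarray
    pool_index: dict[tuple[str, str], int]  # (region, commodity) -> node index
    outputs: np.ndarray | None = None  # reference node outputs (diagnostics)
    _inverse: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        a = self.coefficients
        n = a.shape[0]
        if a.shape != (n, n):
            raise ValidationError("coefficient matrix must be square")
        if n > DENSE_SIZE_CAP:
            raise ValidationError(
                f"system of {n} nodes exceeds the dense solver cap {DENSE_SIZE_CAP}"
            )
        if n:
            radius = float(np.max(np.abs(np.linalg.eigvals(a))))
            if radius >= 1.0 - 1e-12:
                raise NonProductiveError(
                    f"coefficient matrix spectral radius {radius:.6f} >= 1"
                )
        for indicator, e in self.extensions.items():
            if (np.asarray(e) < 0).any():
                raise ValidationError(f"negative extension intensity for {indicator}")

    @classmethod
    def from_coefficients(
        cls,
        coefficients: np.ndarray,
        extensions: Mapping[str, Sequence[float]],
        commodities: Sequence[str] | None = None,
        region: str = "R0",
    ) -> "LeontiefSystem":
        """Wrap a bare A matrix (single region, one node per commodity)."""
        a = np.asarray(coefficients, dtype=float)
        n = a.shape[0]
        commodities = list(commodities) if commodities is not None else [
            f"S{i}" for i in range(n)
        ]
        return cls(
            coefficients=a,
            extensions={k: np.asarray(v, dtype=float) for k, v in extensions.items()},
            node_region=np.array([region] * n),
            node_kind=np.array(["producer"] * n),
            node_commodity=np.array(commodities),
            pool_index={(region, c): i for i, c in enumerate(commodities)},
        )

    @property
    def n_nodes(self) -> int:
        return self.coefficients.shape[0]

    @property
    def leontief_inverse(self) -> np.ndarray:
        """(I - A)^-1, computed once by dense linear solve."""
        if self._inverse is None:
            n = self.n_nodes
            self._inverse = scipy.linalg.solve(np.eye(n) - self.coefficients, np.eye(n))
        return self._inverse

    def solve(self, demand: np.ndarray, method: str = "direct",
              tolerance: float = 1e-12, max_iterations: int = 10_000) -> np.ndarray:
        """Total output x required to serve final demand y.

        ``method="series"`` accumulates the power series sum_k A^k y (the
        independent oracle for the direct solve).
        """
        y = np.asarray(demand, dtype=float)
        if method == "direct":
            return scipy.linalg.solve(np.eye(self.n_nodes) - self.coefficients, y)
        if method == "series":
            term = y.copy()
            x = y.copy()
            for _ in range(max_iterations):
                term = self.coefficients @ term
                x += term
                if np.abs(term).max() <= tolerance:
                    return x
            raise NonProductiveError("power series did not converge")
        raise ValidationError(f"unknown solve method {method!r}")


def _allocation_shares_for_industry(
    outputs: pd.Series, mode: str, prices: pd.Series | None, label: str
) -> pd.Series:
    if mode not in ("mass", "value"):
        raise ConfigurationError(f"allocation mode must be mass or value, got {mode!r}")
    if len(outputs) == 1:  # single-output industries need no price data
        return pd.Series(1.0, index=outputs.index)
    weights = outputs.astype(float)
    if mode == "value":
        if prices is None:
            raise ConfigurationError(
                f"value allocation for {label} requires commodity prices"
            )
        p = prices.reindex(outputs.index)
        if p.isna().any():
            missing = sorted(p[p.isna()].index)
            raise ConfigurationError(f"missing price for outputs {missing} of {label}")
        weights = weights * p
    total = weights.sum()
    if total <= 0:
        raise StructureError(f"{label} has zero total output weight")
    return weights / total


def sut_to_coefficients(sut: SupplyUseSystem, mode: str = "mass") -> LeontiefSystem:
    """Build the node-level coefficient system from supply--use tables.

    Multi-output industries are split into per-commodity producers whose
    inputs and extensions carry the industry's mass or value output share;
    pools link producers, importers and final users per region.
    """
    supply = sut.supply[sut.supply["value"] > 0]
    production = supply.groupby(["region", "commodity"])["value"].sum()
    use_by_ind = sut.use.groupby(["region", "industry"])["value"].sum()
    out_by_ind = supply.groupby(["region", "industry"])["value"].sum()
    for key, used in use_by_ind.items():
        if used > 0 and out_by_ind.get(key, 0.0) <= 0:
            raise StructureError(
                f"industry {key[1]!r} in region {key[0]!r} has inputs but no output"
            )

    # node catalogue ---------------------------------------------------------
    nodes: list[tuple] = []  # ("producer", region, industry, commodity) | ("pool", region, commodity)
    producer_index: dict[tuple[str, str, str], int] = {}
    pool_index: dict[tuple[str, str], int] = {}
    for row in supply.itertuples(index=False):
        key = (row.region, row.industry, row.commodity)
        producer_index[key] = len(nodes)
        nodes.append(("producer",) + key)

    imports: dict[tuple[str, str], pd.Series] = {}
    pool_supply: dict[tuple[str, str], float] = {}
    trade_commodities = set(sut.trade.commodities) if sut.trade is not None else set()
    pool_keys = set(production.index)
    if sut.trade is not None:
        for k in trade_commodities:
            t = sut.trade.flows_of(k)
            inflow = t.sum(axis=0)
            for region in inflow.index[inflow > 0]:
                pool_keys.add((region, k))
    for region, commodity in sorted(pool_keys):
        d = float(production.get((region, commodity), 0.0))
        if commodity in trade_commodities:
            t = sut.trade.flows_of(commodity)
            col = t[region] if region in t.columns else None
            if col is not None:
                inflow = col[col > 0]
                if len(inflow):
                    imports[(region, commodity)] = inflow
                    d += float(inflow.sum())
        if d <= 0:
            continue
        pool_supply[(region, commodity)] = d
        pool_index[(region, commodity)] = len(nodes)
        nodes.append(("pool", region, commodity))

    n = len(nodes)
    a = np.zeros((n, n))
    outputs = np.zeros(n)
    extensions: dict[str, np.ndarray] = {
        q: np.zeros(n) for q in sut.extensions["indicator"].unique()
    }

    # producer columns -------------------------------------------------------
    supply_by_ind = {
        key: grp.set_index("commodity")["value"]
        for key, grp in supply.groupby(["region", "industry"])
    }
    use_rows = {
        key: grp.groupby("commodity")["value"].sum()
        for key, grp in sut.use.groupby(["region", "industry"])
    }
    ext_rows = {
        key: grp.groupby("indicator")["value"].sum()
        for key, grp in sut.extensions.groupby(["region", "industry"])
    }
    for (region, industry), out in supply_by_ind.items():
        shares = _allocation_shares_for_industry(
            out, mode, sut.prices, f"industry {industry!r} in {region!r}"
        )
        inputs = use_rows.get((region, industry))
        exts = ext_rows.get((region, industry))
        for commodity, produced in out.items():
            col = producer_index[(region, industry, commodity)]
            outputs[col] = produced
            share = float(shares[commodity])
            if inputs is not None:
                for input_commodity, amount in inputs.items():
                    if amount <= 0:
                        continue
                    pool = pool_index.get((region, input_commodity))
                    if pool is None:
                        raise StructureError(
                            f"industry {industry!r} in {region!r} uses "
                            f"{input_commodity!r} but the region has no supply of it"
                        )
                    a[pool, col] += share * amount / produced
            if exts is not None:
                for indicator, amount in exts.items():
                    extensions[indicator][col] += share * amount / produced

    # pool columns -----------------------------------------------------------
    for (region, commodity), d in pool_supply.items():
        col = pool_index[(region, commodity)]
        outputs[col] = d
        for (reg2, industry), out in supply_by_ind.items():
            if reg2 == region and commodity in out.index:
                prod_node = producer_index[(region, industry, commodity)]
                a[prod_node, col] += float(out[commodity]) / d
        inflow = imports.get((region, commodity))
        if inflow is not None:
            for origin, amount in inflow.items():
                source = pool_index.get((origin, commodity))
                if source is None:
                    raise StructureError(
                        f"imports of {commodity!r} into {region!r} from "
                        f"{origin!r}, which has no supply pool"
                    )
                a[source, col] += float(amount) / d

    return LeontiefSystem(
        coefficients=a,
        extensions=extensions,
        node_region=np.array([node[1] for node in nodes]),
        node_kind=np.array([node[0] for node in nodes]),
        node_commodity=np.array([node[-1] for node in nodes]),
        pool_index=pool_index,
        outputs=outputs,
    )


def leontief_footprint(
    system: LeontiefSystem,
    demand: pd.DataFrame,
    model_variant: str = "MRIO",
) -> FootprintResult:
    """Footprint of final demand, resolved by consuming region, product and origin.

    ``demand`` is a long frame ``region, commodity, category, value``; the
    footprint of each (region, product) demand cell is the extension applied
    to the total output the demand pulls, grouped by producing-node region.
    """
    if demand.empty:
        return FootprintResult()
    cells = demand.groupby(["region", "commodity"])["value"].sum()
    inverse = system.leontief_inverse
    producers = system.node_kind == "producer"
    regions = system.node_region
    records: list[dict] = []
    for (region, commodity), y in cells.items():
        if y <= 0:
            continue
        idx = system.pool_index.get((region, commodity))
        if idx is None:
            raise IndexingError(
                f"final demand for {commodity!r} in {region!r}, which has no supply"
            )
        x = inverse[:, idx] * float(y)
        for indicator, e in system.extensions.items():
            contrib = e * x
            contrib = np.where(producers, contrib, 0.0)
            if not contrib.any():
                continue
            by_origin = pd.Series(contrib).groupby(regions).sum()
            for origin, value in by_origin.items():
                if value > 0:
                    records.append(
                        {
                            "model_variant": model_variant,
                            "consumer": region,
                            "product": commodity,
                            "origin": origin,
                            "food_class": "unclassified",
                            "indicator": indicator,
                            "value": float(value),
                        }
                    )
    frame = pd.DataFrame.from_records(records)
    if len(frame):
        unknown = set(frame["indicator"]) - set(INDICATORS)
        if unknown:
            raise ValidationError(f"extension indicators {sorted(unknown)} are not supported")
    return FootprintResult(frame) if len(frame) else FootprintResult()


def classify_food(
    result: FootprintResult,
    classes: pd.DataFrame,
    scenario: str,
) -> FootprintResult:
    """Split a footprint into food / non-food under a min or max scenario.

    ``classes`` maps ``commodity -> class`` with classes ``food_certain``,
    ``food_possible`` and ``nonfood``.  The min scenario counts only certain
    food; the max scenario additionally counts possible food.  Food and
    non-food always add up to the unclassified total.
    """
    if scenario not in ("min", "max"):
        raise ConfigurationError(f"scenario must be min or max, got {scenario!r}")
    mapping = classes.set_index("commodity")["class"]
    bad = set(mapping.unique()) - {"food_certain", "food_possible", "nonfood"}
    if bad:
        raise ClassificationError(f"unknown food classes {sorted(bad)}")
    frame = result.frame.copy()
    klass = frame["product"].map(mapping)
    if klass.isna().any():
        missing = sorted(frame.loc[klass.isna(), "product"].unique())
        raise ClassificationError(f"products without a food class: {missing}")
    food = {"min": {"food_certain"}, "max": {"food_certain", "food_possible"}}[scenario]
    frame["food_class"] = np.where(klass.isin(list(food)), "food", "nonfood")
    return FootprintResult(frame)
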