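"""Commodity trees: primary-equivalent conversion, allocation, feed embedding.

A commodity tree is a forest of processing steps.  Each process consumes one
parent commodity and yields one or more child commodities, each with an
extraction rate (tonnes of child per tonne of parent) and a unit price.
Multi-output processes (e.g. crushing soybeans into oil and cake) split the
parent mass — and hence the environmental burden — among their outputs either
by mass or by value.  Converting a derived flow back to primary equivalents
composes, along the path to the primary commodity, the factor

    share_of_output / extraction_rate

so that the complete output bundle of one tonne of parent maps back to
exactly one tonne of parent, regardless of allocation mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import pandas as pd

from .errors import AttributionError, ConfigurationError, MappingError, ValidationError

logger = logging.getLogger(__name__)

MAX_EXTRACTION_RATE = 1.5  # >1 allowed for hydration steps (e.g. beer from barley)


@dataclass(frozen=True)
class ProcessOutput:
    commodity: str
    extraction_rate: float
    price_per_t: float | None


class CommodityTree:
    """Directed processing forest from primary commodities to products.

    Built from a table with columns
    ``process, parent_commodity, child_commodity, extraction_rate, price_per_t``.
    """

    def __init__(self, table: pd.DataFrame):
        required = {
            "process",
            "parent_commodity",
            "child_commodity",
            "extraction_rate",
            "price_per_t",
        }
        missing = required - set(table.columns)
        if missing:
            raise ValidationError(f"commodity tree missing columns {sorted(missing)}")
        self.processes: dict[str, tuple[str, list[ProcessOutput]]] = {}
        self._producing_process: dict[str, str] = {}
        for process, rows in table.groupby("process", sort=True):
            parents = rows["parent_commodity"].unique()
            if len(parents) != 1:
                raise ValidationError(
                    f"process {process!r} has multiple parents {sorted(parents)}"
                )
            outputs = []
            for row in rows.itertuples(index=False):
                rate = float(row.extraction_rate)
                if not (0.0 < rate <= MAX_EXTRACTION_RATE):
                    raise ConfigurationError(
                        f"extraction rate {rate} of {row.child_commodity!r} in "
                        f"process {process!r} outside (0, {MAX_EXTRACTION_RATE}]"
                    )
                price = row.price_per_t
                price = None if pd.isna(price) else float(price)
                if price is not None and price <= 0:
                    raise ConfigurationError(
                        f"non-positive price for {row.child_commodity!r} "
                        f"in process {process!r}"
                    )
                child = str(row.child_commodity)
                if child in self._producing_process:
                    raise ValidationError(
                        f"commodity {child!r} produced by two processes "
                        f"({self._producing_process[child]!r} and {process!r}); "
                        "the tree must be a forest"
                    )
                self._producing_process[child] = str(process)
                outputs.append(ProcessOutput(child, rate, price))
            self.processes[str(process)] = (str(parents[0]), outputs)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        graph = nx.DiGraph()
        for parent, outputs in self.processes.values():
            for out in outputs:
                graph.add_edge(parent, out.commodity)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValidationError(f"commodity tree contains a cycle: {cycle}")
        self.graph = graph

    # -- queries -------------------------------------------------------------
    @property
    def commodities(self) -> set[str]:
        return set(self.graph.nodes)

    def is_derived(self, commodity: str) -> bool:
        return commodity in self._producing_process

    def primaries(self) -> set[str]:
        """Commodities that are never the output of a process."""
        return {c for c in self.graph.nodes if c not in self._producing_process}

    def allocation_shares(self, process: str, mode: str) -> dict[str, float]:
        """Per-output burden shares of a process.

        mass:   share_o = rate_o / sum(rates)
        value:  share_o = rate_o * price_o / sum(rate_q * price_q)
        """
        if process not in self.processes:
            raise MappingError(f"unknown process {process!r}")
        if mode not in ("mass", "value"):
            raise ConfigurationError(f"allocation mode must be mass or value, got {mode!r}")
        _, outputs = self.processes[process]
        if mode == "mass":
            weights = {o.commodity: o.extraction_rate for o in outputs}
        else:
            for o in outputs:
                if o.price_per_t is None:
                    raise ConfigurationError(
                        f"value allocation for process {process!r} requires a "
                        f"price for output {o.commodity!r}"
                    )
            weights = {o.commodity: o.extraction_rate * o.price_per_t for o in outputs}
        total = sum(weights.values())
        if total <= 0:
            raise ConfigurationError(f"process {process!r} has zero total output weight")
        return {commodity: w / total for commodity, w in weights.items()}

    def primary_equivalent_factor(self, commodity: str, mode: str) -> tuple[str, float]:
        """(primary commodity, tonnes of primary per tonne of ``commodity``).

        Composes share/rate along the processing path; a primary commodity
        maps to itself with factor 1.
        """
        factor = 1.0
        current = commodity
        seen = set()
        while current in self._producing_process:
            if current in seen:  # defensive; tree is validated acyclic
                raise MappingError(f"cycle while resolving {commodity!r}")
            seen.add(current)
            process = self._producing_process[current]
            parent, outputs = self.processes[process]
            rate = next(o.extraction_rate for o in outputs if o.commodity == current)
            share = self.allocation_shares(process, mode)[current]
            factor *= share / rate
            current = parent
        return current, factor


def to_primary_equivalents(
    tensor: "TradeTensor",
    tree: CommodityTree,
    mode: str,
    primaries: set[str] | None = None,
    missing: str = "error",
    include_production: bool = True,
) -> "TradeTensor":
    """Convert flows of derived products into primary-commodity equivalents.

    Each tonne of a derived product becomes ``share / extraction_rate`` parent
    tonnes, composed along the path to the primary; primary commodities pass
    through unchanged.  ``primaries`` optionally restricts which commodities
    outside the tree count as primary; others are then either rejected
    (``missing="error"``) or dropped with a warning (``missing="exclude"``).

    When ``include_production`` is False, the production vectors of derived
    commodities are not folded into the primary production (used by the
    physical-tracing pipeline, where processing output would double-count the
    primary harvest already on the books).
    """
    from .tracing import TradeTensor  # local import to avoid a cycle

    if missing not in ("error", "exclude"):
        raise ConfigurationError("missing policy must be 'error' or 'exclude'")
    countries = tensor.countries
    production: dict[str, pd.Series] = {}
    flows: dict[str, pd.DataFrame] = {}

    def _target(commodity: str) -> tuple[str, float] | None:
        if tree.is_derived(commodity):
            return tree.primary_equivalent_factor(commodity, mode)
        if primaries is None or commodity in primaries or commodity in tree.primaries():
            return commodity, 1.0
        if missing == "error":
            raise MappingError(
                f"commodity {commodity!r} has no commodity-tree path and is "
                "not a declared primary"
            )
        logger.warning("dropping untracked commodity %s", commodity)
        return None

    for commodity in tensor.commodities:
        resolved = _target(commodity)
        if resolved is None:
            continue
        primary, factor = resolved
        p, t = tensor.production_of(commodity), tensor.flows_of(commodity)
        is_primary = factor == 1.0 and primary == commodity
        p_add = p * factor if (include_production or is_primary) else p * 0.0
        if primary in production:
            production[primary] = production[primary] + p_add
            flows[primary] = flows[primary] + t * factor
        else:
            production[primary] = p_add
            flows[primary] = t * factor
    return TradeTensor(production, flows, countries=countries)


def embed_feed(
    feed_pool: pd.DataFrame,
    outputs: pd.DataFrame,
    weights: pd.Series | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Distribute per-country feed-pool footprints over livestock products.

    Product ``p`` in country ``c`` receives the fraction
    ``w_p * Q_cp / sum_q(w_q * Q_cq)`` of the country's pool, where ``Q`` are
    product tonnages and ``w`` global product weights.  Country-specific
    weights (a DataFrame with columns ``country, livestock_product, weight``)
    are accepted through the same contract; omitted weights default to
    uniform.

    Parameters
    ----------
    feed_pool
        Columns ``country, indicator, value`` (an optional ``origin`` column
        rides along: pools are split per (country, origin, indicator)).
    outputs
        Columns ``country, livestock_product, quantity_t``.
    weights
        Series indexed by livestock product, or DataFrame with columns
        ``country, livestock_product, weight``.

    Returns
    -------
    DataFrame with columns ``country, livestock_product, indicator,
    [origin,] value``; per country and indicator the values sum to the pool.
    """
    out = outputs.copy()
    if weights is None:
        out["weight"] = 1.0
    elif isinstance(weights, pd.Series):
        out["weight"] = out["livestock_product"].map(weights)
    else:
        out = out.merge(weights, on=["country", "livestock_product"], how="left")
    if out["weight"].isna().any():
        missing = out.loc[out["weight"].isna(), "livestock_product"].unique()
        raise AttributionError(f"no feed weight for products {sorted(missing)}")
    if (out["weight"] < 0).any():
        raise AttributionError("feed weights must be non-negative")
    out["wq"] = out["weight"] * out["quantity_t"]
    denom = out.groupby("country")["wq"].transform("sum")
    pool_countries = set(feed_pool.loc[feed_pool["value"] != 0, "country"])
    dead = pool_countries - set(out.loc[denom > 0, "country"])
    if dead:
        raise AttributionError(
            f"countries with a feed pool but zero total weighted output: {sorted(dead)}"
        )
    out = out[denom > 0].copy()
    out["share"] = out["wq"] / denom[out.index]
    merged = feed_pool.merge(out[["country", "livestock_product", "share"]], on="country")
    merged["value"] = merged["value"] * merged["share"]
    keep = ["country", "livestock_product", "indicator"]
    if "origin" in feed_pool.columns:
        keep.append("origin")
    return merged[keep + ["value"]].reset_index(drop=True)
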