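"""Physical trade tracing: re-export origin resolution and intensity attachment.

The engine formalizes bilateral origin tracing as a linear mixing system.
For one commodity, let P be the production vector and T the bilateral flow
matrix (origin x destination, tonnes).  Each country's supply pool is

    D_i = P_i + sum_j T_ji            (production + imports)

and the export-share matrix B_ji = T_ji / D_j gives the fraction of j's pool
shipped onward to i.  Under proportional mixing — every tonne leaving a pool
carries the pool's origin composition — the embodied-production matrix
(producer x pool holder) is

    F = diag(P) (I - B)^-1

whose column i decomposes D_i by country of primary production.  Consumption
C_i = D_i - exports_i inherits its pool's composition, which yields origin
shares; multiplying attributed tonnes by origin-country yields and water
coefficients turns them into land and water footprints.

Re-export chains of any depth, including cycles, are resolved by the inverse;
a truncated geometric series in B (``method="iterative"``) is exposed both as
a fallback and as an independent oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import DataError, IntensityError, TracingError, ValidationError
from .results import FootprintResult, UNCLASSIFIED

logger = logging.getLogger(__name__)


class TradeTensor:
    """Per-commodity production vectors and bilateral flow matrices.

    Countries are indexed identically across all commodities; all entries are
    non-negative tonnes per year.
    """

    def __init__(
        self,
        production: Mapping[str, pd.Series],
        flows: Mapping[str, pd.DataFrame],
        countries: list[str] | None = None,
    ):
        if countries is None:
            seen: set[str] = set()
            for p in production.values():
                seen |= set(p.index)
            for t in flows.values():
                seen |= set(t.index) | set(t.columns)
            countries = sorted(seen)
        self.countries = list(countries)
        self.production: dict[str, pd.Series] = {}
        self.flows: dict[str, pd.DataFrame] = {}
        commodities = sorted(set(production) | set(flows))
        zero_p = pd.Series(0.0, index=self.countries)
        zero_t = pd.DataFrame(0.0, index=self.countries, columns=self.countries)
        for commodity in commodities:
            p = production.get(commodity)
            p = zero_p.copy() if p is None else p.reindex(self.countries, fill_value=0.0).astype(float)
            t = flows.get(commodity)
            t = (
                zero_t.copy()
                if t is None
                else t.reindex(index=self.countries, columns=self.countries, fill_value=0.0).astype(float)
            )
            if (p < 0).any() or (t.to_numpy() < 0).any():
                raise ValidationError(f"negative quantities for commodity {commodity!r}")
            self.production[commodity] = p
            self.flows[commodity] = t

    @classmethod
    def from_frames(
        cls,
        production: pd.DataFrame,
        trade: pd.DataFrame | None = None,
        countries: list[str] | None = None,
    ) -> "TradeTensor":
        """Build from long tables ``commodity,country,quantity_t`` and
        ``commodity,origin,destination,quantity_t``."""
        prod = {
            k: grp.groupby("country")["quantity_t"].sum()
            for k, grp in production.groupby("commodity")
        }
        flows: dict[str, pd.DataFrame] = {}
        if trade is not None and len(trade):
            for k, grp in trade.groupby("commodity"):
                flows[k] = (
                    grp.pivot_table(
                        index="origin",
                        columns="destination",
                        values="quantity_t",
                        aggfunc="sum",
                        fill_value=0.0,
                    )
                )
        return cls(prod, flows, countries=countries)

    @property
    def commodities(self) -> list[str]:
        return sorted(self.production)

    def production_of(self, commodity: str) -> pd.Series:
        return self.production[commodity]

    def flows_of(self, commodity: str) -> pd.DataFrame:
        return self.flows[commodity]

    def items(self) -> Iterator[tuple[str, pd.Series, pd.DataFrame]]:
        for k in self.commodities:
            yield k, self.production[k], self.flows[k]


@dataclass
class ShareSystem:
    """The reconciled linear mixing system of one commodity."""

    commodity: str
    countries: list[str]
    production: np.ndarray  # P
    supply: np.ndarray  # D_i = P_i + imports_i (post reconciliation)
    exports: np.ndarray  # row sums of T (post reconciliation)
    share_matrix: np.ndarray  # B_ji = T_ji / D_j
    flows: np.ndarray  # reconciled T
    reconciliation: list[dict] = field(default_factory=list)


@dataclass
class OriginShares:
    """Per consuming country, the origin composition of its supply pool."""

    commodity: str
    countries: list[str]
    shares: np.ndarray  # producer (row) x consumer (column)
    embodied: np.ndarray  # F = diag(P) (I-B)^-1

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.shares, index=self.countries, columns=self.countries)


def build_share_system(
    tensor: TradeTensor,
    commodity: str,
    max_iterations: int = 10_000,
) -> ShareSystem:
    """Compute supply pools and export shares, reconciling excess exports.

    When a country's reported exports exceed its supply (inconsistent data),
    its export row is scaled down proportionally so the row sum of B equals
    1 - 1e-9; scaling reduces downstream imports, so the adjustment iterates
    to a fixed point.  Each adjustment is logged and recorded.
    """
    p = tensor.production_of(commodity).to_numpy(dtype=float)
    t = tensor.flows_of(commodity).to_numpy(dtype=float).copy()
    countries = tensor.countries
    log: list[dict] = []
    for _ in range(max_iterations):
        supply = p + t.sum(axis=0)
        exports = t.sum(axis=1)
        limit = supply * (1.0 - 1e-9)
        over = exports > limit
        if not over.any():
            break
        for j in np.flatnonzero(over):
            if supply[j] <= 0:
                raise DataError(
                    f"{commodity}: country {countries[j]!r} exports "
                    f"{exports[j]:.6g} t with zero supply"
                )
            factor = limit[j] / exports[j]
            log.append(
                {
                    "commodity": commodity,
                    "country": countries[j],
                    "exports": float(exports[j]),
                    "supply": float(supply[j]),
                    "scale": float(factor),
                }
            )
            t[j, :] *= factor
    else:
        raise DataError(f"{commodity}: export reconciliation did not converge")
    for entry in log:
        logger.warning(
            "%s: scaled exports of %s by %.6f (exports %.6g > supply %.6g)",
            entry["commodity"], entry["country"], entry["scale"],
            entry["exports"], entry["supply"],
        )
    supply = p + t.sum(axis=0)
    exports = t.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(supply[:, None] > 0, t / supply[:, None], 0.0)
    if ((t.sum(axis=1) > 0) & (supply <= 0)).any():
        bad = [countries[j] for j in np.flatnonzero((t.sum(axis=1) > 0) & (supply <= 0))]
        raise DataError(f"{commodity}: exports from countries with zero supply: {bad}")
    return ShareSystem(
        commodity=commodity,
        countries=list(countries),
        production=p,
        supply=supply,
        exports=exports,
        share_matrix=b,
        flows=t,
        reconciliation=log,
    )


def trace_origins(
    system: ShareSystem,
    method: str = "direct",
    tolerance: float = 1e-10,
    max_iterations: int = 10_000,
) -> OriginShares:
    """Resolve the origin composition of every country's supply pool.

    ``method="direct"`` solves F (I - B) = diag(P) with a dense linear solve;
    ``method="iterative"`` accumulates the geometric series
    diag(P) (I + B + B^2 + ...) until the increment drops below ``tolerance``.
    """
    p, b, d = system.production, system.share_matrix, system.supply
    n = len(p)
    if p.sum() <= 0 and d.sum() > 0:
        raise TracingError(
            f"{system.commodity}: traded commodity has no production anywhere"
        )
    if method == "direct":
        # F (I - B) = diag(P)  <=>  (I - B)^T F^T = diag(P)
        try:
            f = scipy.linalg.solve(np.eye(n) - b.T, np.diag(p)).T
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise TracingError(f"{system.commodity}: singular mixing system") from exc
    elif method == "iterative":
        term = np.diag(p).astype(float)
        f = term.copy()
        for _ in range(max_iterations):
            term = term @ b
            f += term
            if np.abs(term).max() <= tolerance:
                break
        else:
            raise TracingError(f"{system.commodity}: series did not converge")
    else:
        raise ValidationError(f"unknown tracing method {method!r}")
    f = np.clip(f, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        shares = np.where(d[None, :] > 0, f / d[None, :], 0.0)
    return OriginShares(
        commodity=system.commodity,
        countries=system.countries,
        shares=shares,
        embodied=f,
    )


def origin_resolved_consumption(
    shares: OriginShares, system: ShareSystem
) -> pd.DataFrame:
    """Attribute each country's apparent consumption to producing countries.

    Consumption is supply minus exports, clipped at zero with a logged
    residual.  Returns a long table ``commodity, consumer, origin, tonnes``
    containing only positive attributions.
    """
    consumption = system.supply - system.exports
    negative = consumption < -1e-9 * np.maximum(system.supply, 1.0)
    if negative.any():
        for j in np.flatnonzero(negative):
            logger.warning(
                "%s: negative apparent consumption %.6g in %s clipped to 0",
                system.commodity, consumption[j], system.countries[j],
            )
    consumption = np.clip(consumption, 0.0, None)
    attributed = shares.shares * consumption[None, :]
    origin_idx, consumer_idx = np.nonzero(attributed > 0)
    return pd.DataFrame(
        {
            "commodity": system.commodity,
            "consumer": [system.countries[i] for i in consumer_idx],
            "origin": [system.countries[m] for m in origin_idx],
            "tonnes": attributed[origin_idx, consumer_idx],
        }
    )


def attach_intensities(
    consumption: pd.DataFrame,
    yields: pd.DataFrame,
    wf_coefficients: pd.DataFrame,
    model_variant: str = "PHYS",
    food_class: str = UNCLASSIFIED,
) -> FootprintResult:
    """Convert origin-resolved tonnes into land and water footprints.

    Land uses the *origin* country's yield: LF_ha = tonnes / yield(origin).
    Water uses the origin's per-tonne coefficients: WF = tonnes * m3/t, green
    and blue carried separately.

    Parameters
    ----------
    consumption
        Long table ``commodity, consumer, origin, tonnes``.
    yields
        ``commodity, country, yield_t_per_ha``.
    wf_coefficients
        ``commodity, country, green_m3_per_t, blue_m3_per_t``.
    """
    if consumption.empty:
        return FootprintResult()
    merged = consumption.merge(
        yields.rename(columns={"country": "origin"}),
        on=["commodity", "origin"],
        how="left",
    ).merge(
        wf_coefficients.rename(columns={"country": "origin"}),
        on=["commodity", "origin"],
        how="left",
    )
    positive = merged["tonnes"] > 0
    bad_yield = positive & (~(merged["yield_t_per_ha"] > 0))
    if bad_yield.any():
        offenders = merged.loc[bad_yield, ["commodity", "origin"]].drop_duplicates()
        raise IntensityError(
            "missing or zero yield for "
            + ", ".join(f"({r.commodity}, {r.origin})" for r in offenders.itertuples())
        )
    bad_wf = positive & (
        merged["green_m3_per_t"].isna() | merged["blue_m3_per_t"].isna()
    )
    if bad_wf.any():
        offenders = merged.loc[bad_wf, ["commodity", "origin"]].drop_duplicates()
        raise IntensityError(
            "missing water coefficient for "
            + ", ".join(f"({r.commodity}, {r.origin})" for r in offenders.itertuples())
        )
    pieces = []
    for indicator, values in (
        ("LF_crop_ha", merged["tonnes"] / merged["yield_t_per_ha"]),
        ("WF_green_m3", merged["tonnes"] * merged["green_m3_per_t"]),
        ("WF_blue_m3", merged["tonnes"] * merged["blue_m3_per_t"]),
    ):
        piece = pd.DataFrame(
            {
                "model_variant": model_variant,
                "consumer": merged["consumer"],
                "product": merged["commodity"],
                "origin": merged["origin"],
                "food_class": food_class,
                "indicator": indicator,
                "value": values,
            }
        )
        pieces.append(piece[piece["value"] > 0])
    return FootprintResult(pd.concat(pieces, ignore_index=True))
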