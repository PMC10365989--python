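"""Reading and writing the pipeline's tabular dialects.

All tables are comma-delimited UTF-8 text with one header row, in long
format; units are fixed per column (tonnes/yr, ha, km2, t/km2, m3/t, m3/ha,
persons) and never stored per row.  Country and commodity codes are opaque
short strings; the production table doubles as the registry of valid codes,
optionally extended by the commodity tree.  Every load logs file digests so
runs are attributable to their exact inputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .errors import ReferentialError, SchemaError, ValidationError
from .results import COLUMNS as RESULT_COLUMNS, FootprintResult
from .tracing import TradeTensor

logger = logging.getLogger(__name__)

#: table role -> (default filename, required columns, non-negative columns)
TABLE_SCHEMAS: dict[str, tuple[str, list[str], list[str]]] = {
    "production": ("production.csv", ["commodity", "country", "quantity_t"], ["quantity_t"]),
    "trade": ("trade.csv", ["commodity", "origin", "destination", "quantity_t"], ["quantity_t"]),
    "commodity_tree": (
        "commodity_tree.csv",
        ["process", "parent_commodity", "child_commodity", "extraction_rate", "price_per_t"],
        ["extraction_rate"],
    ),
    "yields": ("yields.csv", ["commodity", "country", "yield_t_per_ha"], ["yield_t_per_ha"]),
    "wf_coefficients": (
        "wf_coefficients.csv",
        ["commodity", "country", "green_m3_per_t", "blue_m3_per_t"],
        ["green_m3_per_t", "blue_m3_per_t"],
    ),
    "feed_use": ("feed_use.csv", ["country", "feed_commodity", "quantity_t"], ["quantity_t"]),
    "feed_weights": ("feed_weights.csv", ["livestock_product", "weight"], ["weight"]),
    "grass_intake": ("grass_intake.csv", ["country", "quantity_t"], ["quantity_t"]),
    "grassland_grid": (
        "grassland_grid.csv",
        ["cell_id", "country", "cell_area_km2", "pasture_fraction", "anpp_t_per_km2"],
        ["cell_area_km2", "pasture_fraction", "anpp_t_per_km2"],
    ),
    "et_rates": ("et_rates.csv", ["country", "et_green_m3_per_ha"], ["et_green_m3_per_ha"]),
    "population": ("population.csv", ["country", "population"], ["population"]),
    "supply": ("supply.csv", ["region", "industry", "commodity", "value"], ["value"]),
    "use": ("use.csv", ["region", "industry", "commodity", "value"], ["value"]),
    "final_demand": ("final_demand.csv", ["region", "commodity", "category", "value"], ["value"]),
    "extensions": ("extensions.csv", ["region", "industry", "indicator", "value"], ["value"]),
    "food_classes": ("food_classes.csv", ["commodity", "class"], []),
    "region_map": ("region_map.csv", ["country", "continent"], []),
    "commodity_groups": ("commodity_groups.csv", ["commodity", "group"], []),
}

REQUIRED_ROLES = {"production"}


@dataclass
class WorldDataset:
    """All parsed tables of one world, with provenance digests."""

    production: pd.DataFrame
    trade: pd.DataFrame | None = None
    commodity_tree: pd.DataFrame | None = None
    yields: pd.DataFrame | None = None
    wf_coefficients: pd.DataFrame | None = None
    feed_use: pd.DataFrame | None = None
    feed_weights: pd.DataFrame | None = None
    grass_intake: pd.DataFrame | None = None
    grassland_grid: pd.DataFrame | None = None
    et_rates: pd.DataFrame | None = None
    population: pd.DataFrame | None = None
    supply: pd.DataFrame | None = None
    use: pd.DataFrame | None = None
    final_demand: pd.DataFrame | None = None
    extensions: pd.DataFrame | None = None
    food_classes: pd.DataFrame | None = None
    region_map: pd.DataFrame | None = None
    commodity_groups: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {}
        for f in dataclass_fields(self):
            if f.name == "provenance":
                continue
            table = getattr(self, f.name)
            if table is not None:
                out[f.name] = table
        return out

    @property
    def countries(self) -> set[str]:
        return set(self.production["country"])

    @property
    def commodities(self) -> set[str]:
        registry = set(self.production["commodity"])
        if self.commodity_tree is not None:
            registry |= set(self.commodity_tree["parent_commodity"])
            registry |= set(self.commodity_tree["child_commodity"])
        return registry

    def trade_tensor(self, commodities: list[str] | None = None) -> TradeTensor:
        """Production + bilateral flows as a :class:`TradeTensor`."""
        production = self.production
        trade = self.trade
        if commodities is not None:
            production = production[production["commodity"].isin(commodities)]
            if trade is not None:
                trade = trade[trade["commodity"].isin(commodities)]
        return TradeTensor.from_frames(production, trade, countries=sorted(self.countries))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _read_table(role: str, path: Path) -> pd.DataFrame:
    filename, columns, nonneg = TABLE_SCHEMAS[role]
    if not path.exists():
        raise SchemaError(f"{role}: file {path} does not exist")
    table = pd.read_csv(path)
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"{role}: missing columns {missing} in {path}")
    for column in nonneg:
        values = pd.to_numeric(table[column], errors="coerce")
        if (values.isna() & table[column].notna()).any():
            raise ValidationError(f"{role}: non-numeric entries in column {column!r}")
        if (values.dropna() < 0).any():
            raise ValidationError(f"{role}: negative values in column {column!r}")
    return table


def _cross_validate(dataset: WorldDataset) -> None:
    countries = dataset.countries
    commodities = dataset.commodities
    if dataset.trade is not None and len(dataset.trade):
        bad_countries = (
            set(dataset.trade["origin"]) | set(dataset.trade["destination"])
        ) - countries
        bad_commodities = set(dataset.trade["commodity"]) - commodities
        offenders = sorted(bad_countries) + sorted(bad_commodities)
        if offenders:
            raise ReferentialError(
                f"trade references codes absent from the registry: {offenders}"
            )
    for role in ("yields", "wf_coefficients", "feed_use", "grass_intake",
                 "et_rates", "population"):
        table = getattr(dataset, role)
        if table is None or not len(table):
            continue
        col = "country"
        bad = set(table[col]) - countries
        if bad:
            raise ReferentialError(
                f"{role} references countries absent from the registry: {sorted(bad)}"
            )


def load_dataset(source: Mapping[str, str | Path] | str | Path) -> WorldDataset:
    """Load a table bundle from a role->path mapping or a directory.

    A directory is expanded to the default filenames; files absent for
    optional roles yield ``None`` tables.  Keys are cross-validated: codes
    used in trade and per-country tables must appear in the registry
    (production plus the commodity tree).
    """
    if isinstance(source, (str, Path)):
        directory = Path(source)
        path_map = {
            role: directory / filename
            for role, (filename, _, _) in TABLE_SCHEMAS.items()
            if (directory / filename).exists() or role in REQUIRED_ROLES
        }
    else:
        path_map = {role: Path(p) for role, p in source.items()}
        unknown = set(path_map) - set(TABLE_SCHEMAS)
        if unknown:
            raise SchemaError(f"unknown table roles {sorted(unknown)}")
    for role in REQUIRED_ROLES:
        if role not in path_map:
            raise SchemaError(f"required table {role!r} not supplied")
    kwargs: dict[str, pd.DataFrame] = {}
    provenance: dict[str, str] = {}
    for role, path in path_map.items():
        kwargs[role] = _read_table(role, path)
        provenance[role] = _digest(path)
        logger.info("loaded %s from %s (sha256 %.12s)", role, path, provenance[role])
    dataset = WorldDataset(provenance=provenance, **kwargs)
    _cross_validate(dataset)
    return dataset


def write_dataset(dataset: WorldDataset, directory: str | Path) -> dict[str, Path]:
    """Write every present table to its default filename under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for role, table in dataset.tables().items():
        filename, columns, _ = TABLE_SCHEMAS[role]
        path = directory / filename
        table.loc[:, [c for c in table.columns if c in columns]].to_csv(path, index=False)
        written[role] = path
    return written


def write_result(result: FootprintResult, path: str | Path) -> None:
    """Write a footprint result as a long CSV; re-reading round-trips values."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    result.frame.to_csv(path, index=False)


def read_result(path: str | Path) -> FootprintResult:
    frame = pd.read_csv(path)
    if frame.empty and list(frame.columns) == RESULT_COLUMNS:
        return FootprintResult()
    return FootprintResult(frame)


def read_config(path: str | Path) -> dict:
    """Read a structured YAML config file (sections ``run``, ``world``, ``paths``)."""
    with open(path, "r", encoding="utf-8") as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise SchemaError("config file must contain a mapping")
    return data
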