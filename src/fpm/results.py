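"""The long-format footprint container shared by every engine.

A :class:`FootprintResult` is a thin wrapper around a tidy DataFrame with one
row per (model variant, consumer, product, origin, food class, indicator).
Indicators are fixed: cropland area in hectares, grazing land in hectares,
and green/blue water in cubic metres.  A total water footprint is never
stored; it is always derived as green + blue.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

INDICATORS = ("LF_crop_ha", "LF_grazing_ha", "WF_green_m3", "WF_blue_m3")
#: water colour of each water indicator; land indicators are absent.
WATER_COLOUR = {"WF_green_m3": "green", "WF_blue_m3": "blue"}

COLUMNS = [
    "model_variant",
    "consumer",
    "product",
    "origin",
    "food_class",
    "indicator",
    "value",
]

UNCLASSIFIED = "unclassified"


class FootprintResult:
    """Footprints indexed by consumer, product, origin, food class, indicator.

    Values are non-negative, in the fixed per-indicator units (ha, m^3).
    """

    def __init__(self, frame: pd.DataFrame | None = None):
        if frame is None:
            frame = pd.DataFrame(columns=COLUMNS)
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"footprint frame missing columns {missing}")
        frame = frame.loc[:, COLUMNS].copy()
        frame["value"] = frame["value"].astype(float)
        bad = frame["indicator"][~frame["indicator"].isin(INDICATORS)].unique()
        if len(bad):
            raise ValidationError(f"unknown indicators {sorted(bad)}")
        if (frame["value"] < -1e-12).any():
            raise ValidationError("footprint values must be non-negative")
        frame.loc[frame["value"] < 0, "value"] = 0.0
        self.frame = frame.reset_index(drop=True)

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "FootprintResult":
        return cls(pd.DataFrame.from_records(list(records), columns=COLUMNS))

    @classmethod
    def concat(cls, results: Sequence["FootprintResult"]) -> "FootprintResult":
        if not results:
            return cls()
        return cls(pd.concat([r.frame for r in results], ignore_index=True))

    # -- basic queries --------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def empty(self) -> bool:
        return self.frame.empty

    def total(self, by: Sequence[str] | None = None) -> pd.Series | float:
        """Sum of values, optionally grouped by a subset of the key columns."""
        if by is None:
            return float(self.frame["value"].sum())
        return self.frame.groupby(list(by), sort=True)["value"].sum()

    def filter(self, **kwargs) -> "FootprintResult":
        """Subset by exact column values, e.g. ``filter(indicator="WF_blue_m3")``."""
        mask = pd.Series(True, index=self.frame.index)
        for column, value in kwargs.items():
            if column not in COLUMNS:
                raise ValidationError(f"unknown filter column {column!r}")
            if isinstance(value, (list, tuple, set, frozenset)):
                mask &= self.frame[column].isin(list(value))
            else:
                mask &= self.frame[column] == value
        return FootprintResult(self.frame[mask])

    def with_variant(self, variant: str) -> "FootprintResult":
        frame = self.frame.copy()
        frame["model_variant"] = variant
        return FootprintResult(frame)

    def collapse(self) -> "FootprintResult":
        """Merge duplicate keys by summing their values."""
        keys = [c for c in COLUMNS if c != "value"]
        frame = self.frame.groupby(keys, as_index=False, sort=True)["value"].sum()
        return FootprintResult(frame)

    def allclose(self, other: "FootprintResult", rtol: float = 1e-9,
                 atol: float = 1e-9) -> bool:
        keys = [c for c in COLUMNS if c != "value"]
        a = self.collapse().frame.set_index(keys)["value"]
        b = other.collapse().frame.set_index(keys)["value"]
        joined = a.to_frame("a").join(b.to_frame("b"), how="outer").fillna(0.0)
        return bool(np.allclose(joined["a"], joined["b"], rtol=rtol, atol=atol))

    def summary(self) -> pd.DataFrame:
        """Per-variant totals by indicator and food class (wide, for display)."""
        table = (
            self.frame.groupby(["model_variant", "indicator", "food_class"])["value"]
            .sum()
            .unstack("indicator", fill_value=0.0)
        )
        return table

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        variants = sorted(self.frame["model_variant"].unique())
        return (
            f"<FootprintResult rows={len(self.frame)} variants={variants} "
            f"total={self.frame['value'].sum():.6g}>"
        )
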