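"""Run configuration shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

from .errors import ConfigurationError

ALLOCATION_MODES = ("mass", "value")
FOOD_SCENARIOS = ("min", "max")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a single accounting run.

    Parameters
    ----------
    scenario_id
        Free-form label carried into logs and result tables.
    allocation_mode
        How multi-output processes split their inputs and burdens among
        outputs: ``"mass"`` (by output tonnage) or ``"value"`` (by output
        tonnage times price).
    food_scenario
        Food classification scenario: ``"min"`` counts only commodities that
        are certainly food; ``"max"`` additionally counts commodities that
        possibly include food.
    npp_usable_fraction
        Fraction of aboveground net primary production on pasture that
        livestock can at most consume (default 0.75).
    land_cap_fraction
        Grazing land footprint of a country is capped at this fraction of
        its available land area (default 0.80).
    days_per_year
        Days used in per-capita water conversions (365 or 366).
    solve_tolerance
        Convergence tolerance of iterative linear solves.
    max_iterations
        Iteration cap for fixed-point solves and reconciliation loops.
    random_seed
        Seed for any stochastic component of the run.
    grazing_wf_uses_cap
        If True (default) grazing green water is computed from the capped
        land footprint; if False from the uncapped intake/productivity area.
    untracked_commodities
        Policy for traded commodities with no commodity-tree path:
        ``"error"`` raises, ``"exclude"`` drops them with a warning.
    """

    scenario_id: str = "default"
    allocation_mode: str = "mass"
    food_scenario: str = "min"
    npp_usable_fraction: float = 0.75
    land_cap_fraction: float = 0.80
    days_per_year: int = 365
    solve_tolerance: float = 1e-10
    max_iterations: int = 10_000
    random_seed: int = 0
    grazing_wf_uses_cap: bool = True
    untracked_commodities: str = "error"

    def __post_init__(self) -> None:
        if self.allocation_mode not in ALLOCATION_MODES:
            raise ConfigurationError(
                f"allocation_mode must be one of {ALLOCATION_MODES}, "
                f"got {self.allocation_mode!r}"
            )
        if self.food_scenario not in FOOD_SCENARIOS:
            raise ConfigurationError(
                f"food_scenario must be one of {FOOD_SCENARIOS}, "
                f"got {self.food_scenario!r}"
            )
        for name in ("npp_usable_fraction", "land_cap_fraction"):
            value = getattr(self, name)
            if not (0.0 < value <= 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1], got {value}")
        if self.days_per_year not in (365, 366):
            raise ConfigurationError(
                f"days_per_year must be 365 or 366, got {self.days_per_year}"
            )
        if self.solve_tolerance <= 0:
            raise ConfigurationError("solve_tolerance must be positive")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")
        if self.untracked_commodities not in ("error", "exclude"):
            raise ConfigurationError(
                "untracked_commodities must be 'error' or 'exclude'"
            )

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))
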