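import pandas as pd
import pytest

from fpm import RunConfig, WorldParams, generate_world
from fpm.commodities import CommodityTree


@pytest.fixture(scope="session")
def default_params() -> WorldParams:
    return WorldParams(
        n_countries=8,
        n_crops=5,
        n_livestock=2,
        n_processed=2,
        trade_density=0.35,
        reexport_depth=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def world(default_params, default_config):
    """A mid-sized world with crops, processing, livestock and grazing."""
    return generate_world(default_params, default_config)


@pytest.fixture(scope="session")
def dataset(world):
    return world[0]


@pytest.fixture(scope="session")
def ground_truth(world):
    return world[1]


@pytest.fixture()
def crush_tree() -> CommodityTree:
    """A soy-style crush: one tonne of beans -> 0.18 t oil + 0.79 t cake."""
    return CommodityTree(
        pd.DataFrame(
            {
                "process": ["crush", "crush"],
                "parent_commodity": ["beans", "beans"],
                "child_commodity": ["oil", "cake"],
                "extraction_rate": [0.18, 0.79],
                "price_per_t": [800.0, 350.0],
            }
        )
    )
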