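"""Commodity-tree conversion, allocation shares and feed embedding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fpm.commodities import CommodityTree, embed_feed, to_primary_equivalents
from fpm.errors import AttributionError, ConfigurationError, MappingError, ValidationError
from fpm.tracing import TradeTensor


class TestAllocationShares:
    def test_mass_shares_are_rate_fractions(self, crush_tree):
        shares = crush_tree.allocation_shares("crush", "mass")
        assert shares["oil"] == pytest.approx(0.18 / 0.97, abs=1e-12)
        assert shares["cake"] == pytest.approx(0.79 / 0.97, abs=1e-12)

    def test_value_shares_weight_by_price(self, crush_tree):
        shares = crush_tree.allocation_shares("crush", "value")
        # oil: 0.18*800 = 144; cake: 0.79*350 = 276.5; total 420.5
        assert shares["oil"] == pytest.approx(144.0 / 420.5, abs=1e-12)
        assert shares["cake"] == pytest.approx(276.5 / 420.5, abs=1e-12)

    def test_shares_sum_to_one(self, crush_tree):
        for mode in ("mass", "value"):
            assert sum(crush_tree.allocation_shares("crush", mode).values()) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_equal_prices_make_value_equal_mass(self):
        tree = CommodityTree(
            pd.DataFrame(
                {
                    "process": ["p", "p"],
                    "parent_commodity": ["a", "a"],
                    "child_commodity": ["x", "y"],
                    "extraction_rate": [0.3, 0.5],
                    "price_per_t": [100.0, 100.0],
                }
            )
        )
        assert tree.allocation_shares("p", "mass") == pytest.approx(
            tree.allocation_shares("p", "value")
        )

    def test_missing_price_in_value_mode_names_output(self):
        tree = CommodityTree(
            pd.DataFrame(
                {
                    "process": ["p", "p"],
                    "parent_commodity": ["a", "a"],
                    "child_commodity": ["x", "y"],
                    "extraction_rate": [0.3, 0.5],
                    "price_per_t": [100.0, np.nan],
                }
            )
        )
        with pytest.raises(ConfigurationError, match="y"):
            tree.allocation_shares("p", "value")

    @settings(derandomize=True, max_examples=60)
    @given(
        rate_main=st.floats(0.1, 0.8),
        rate_by=st.floats(0.05, 0.6),
        price_main=st.floats(100.0, 5000.0),
        discount=st.floats(0.01, 0.99),
    )
    def test_cheaper_byproduct_gets_smaller_value_share(
        self, rate_main, rate_by, price_main, discount
    ):
        """A by-product priced below the main product carries strictly less of
        the burden under value allocation than under mass allocation."""
        tree = CommodityTree(
            pd.DataFrame(
                {
                    "process": ["p", "p"],
                    "parent_commodity": ["parent", "parent"],
                    "child_commodity": ["main", "by"],
                    "extraction_rate": [rate_main, rate_by],
                    "price_per_t": [price_main, price_main * discount],
                }
            )
        )
        mass = tree.allocation_shares("p", "mass")
        value = tree.allocation_shares("p", "value")
        assert value["by"] < mass["by"]
        assert value["main"] > mass["main"]
        assert sum(value.values()) == pytest.approx(1.0, abs=1e-12)


class TestPrimaryEquivalents:
    def _tensor(self, commodity, origin_qty):
        production = pd.DataFrame(
            [{"commodity": commodity, "country": "A", "quantity_t": origin_qty}]
        )
        trade = pd.DataFrame(
            [{"commodity": commodity, "origin": "A", "destination": "B",
              "quantity_t": origin_qty}]
        )
        return TradeTensor.from_frames(production, trade, countries=["A", "B"])

    def test_derived_flow_expands_by_share_over_rate(self, crush_tree):
        tensor = self._tensor("oil", 0.18)
        converted = to_primary_equivalents(tensor, crush_tree, "mass")
        # 0.18 t oil / rate 0.18 * mass share 0.18/0.97
        expected = 0.18 / 0.97
        assert converted.flows_of("beans").loc["A", "B"] == pytest.approx(expected, rel=1e-12)

    def test_primary_flow_passes_through(self, crush_tree):
        tensor = self._tensor("beans", 5.0)
        converted = to_primary_equivalents(tensor, crush_tree, "mass")
        assert converted.flows_of("beans").loc["A", "B"] == pytest.approx(5.0)

    @pytest.mark.parametrize("mode", ["mass", "value"])
    def test_complete_bundle_conserves_parent_mass(self, crush_tree, mode):
        """The full crush output of 1 t of beans maps back to exactly 1 t."""
        production = pd.DataFrame(
            [
                {"commodity": "oil", "country": "A", "quantity_t": 0.18},
                {"commodity": "cake", "country": "A", "quantity_t": 0.79},
            ]
        )
        trade = pd.DataFrame(
            [
                {"commodity": "oil", "origin": "A", "destination": "B", "quantity_t": 0.18},
                {"commodity": "cake", "origin": "A", "destination": "B", "quantity_t": 0.79},
            ]
        )
        tensor = TradeTensor.from_frames(production, trade, countries=["A", "B"])
        converted = to_primary_equivalents(tensor, crush_tree, mode)
        assert converted.flows_of("beans").loc["A", "B"] == pytest.approx(1.0, rel=1e-12)

    def test_unknown_commodity_policy(self, crush_tree):
        tensor = self._tensor("mystery", 1.0)
        with pytest.raises(MappingError, match="mystery"):
            to_primary_equivalents(tensor, crush_tree, "mass", primaries={"beans"})
        converted = to_primary_equivalents(
            tensor, crush_tree, "mass", primaries={"beans"}, missing="exclude"
        )
        assert "mystery" not in converted.commodities

    def test_two_stage_chain_composes(self):
        """Flour -> bread style two-step chains compose share/rate factors."""
        tree = CommodityTree(
            pd.DataFrame(
                {
                    "process": ["mill", "bake"],
                    "parent_commodity": ["wheat", "flour"],
                    "child_commodity": ["flour", "bread"],
                    "extraction_rate": [0.8, 1.2],
                    "price_per_t": [300.0, 900.0],
                }
            )
        )
        primary, factor = tree.primary_equivalent_factor("bread", "mass")
        assert primary == "wheat"
        assert factor == pytest.approx((1.0 / 1.2) * (1.0 / 0.8), rel=1e-12)

    def test_cycle_is_rejected(self):
        with pytest.raises(ValidationError, match="cycle|forest"):
            CommodityTree(
                pd.DataFrame(
                    {
                        "process": ["p1", "p2"],
                        "parent_commodity": ["a", "b"],
                        "child_commodity": ["b", "a"],
                        "extraction_rate": [0.5, 0.5],
                        "price_per_t": [1.0, 1.0],
                    }
                )
            )


class TestEmbedFeed:
    def _pool(self, value=120.0):
        return pd.DataFrame(
            [{"country": "A", "indicator": "LF_crop_ha", "value": value}]
        )

    def test_single_product_receives_whole_pool(self):
        outputs = pd.DataFrame(
            [{"country": "A", "livestock_product": "milk", "quantity_t": 7.0}]
        )
        out = embed_feed(self._pool(), outputs)
        assert out["value"].sum() == pytest.approx(120.0)

    def test_equal_weights_split_by_tonnage(self):
        outputs = pd.DataFrame(
            [
                {"country": "A", "livestock_product": "milk", "quantity_t": 1.0},
                {"country": "A", "livestock_product": "beef", "quantity_t": 3.0},
            ]
        )
        out = embed_feed(self._pool(100.0), outputs).set_index("livestock_product")["value"]
        assert out["milk"] == pytest.approx(25.0)
        assert out["beef"] == pytest.approx(75.0)

    def test_weight_scale_invariance(self):
        outputs = pd.DataFrame(
            [
                {"country": "A", "livestock_product": "milk", "quantity_t": 2.0},
                {"country": "A", "livestock_product": "beef", "quantity_t": 5.0},
            ]
        )
        w1 = pd.Series({"milk": 0.4, "beef": 1.7})
        a = embed_feed(self._pool(), outputs, w1).set_index("livestock_product")["value"]
        b = embed_feed(self._pool(), outputs, 10.0 * w1).set_index("livestock_product")["value"]
        pd.testing.assert_series_equal(a, b)

    def test_all_zero_weights_with_pool_raise(self):
        outputs = pd.DataFrame(
            [{"country": "A", "livestock_product": "milk", "quantity_t": 7.0}]
        )
        with pytest.raises(AttributionError):
            embed_feed(self._pool(), outputs, pd.Series({"milk": 0.0}))

    @settings(derandomize=True, max_examples=40)
    @given(
        pools=st.lists(st.floats(0.1, 1e6), min_size=1, max_size=3),
        tonnages=st.lists(st.floats(0.1, 1e4), min_size=1, max_size=4),
        weights=st.lists(st.floats(0.01, 10.0), min_size=4, max_size=4),
    )
    def test_attribution_conserves_pool(self, pools, tonnages, weights):
        """Per country and indicator the attributed amounts sum to the pool."""
        indicators = ["LF_crop_ha", "WF_green_m3", "WF_blue_m3"]
        pool = pd.DataFrame(
            [
                {"country": "A", "indicator": indicators[i], "value": v}
                for i, v in enumerate(pools)
            ]
        )
        outputs = pd.DataFrame(
            [
                {"country": "A", "livestock_product": f"p{i}", "quantity_t": q}
                for i, q in enumerate(tonnages)
            ]
        )
        series = pd.Series({f"p{i}": weights[i] for i in range(len(tonnages))})
        out = embed_feed(pool, outputs, series)
        sums = out.groupby("indicator")["value"].sum()
        for i, v in enumerate(pools):
            assert sums[indicators[i]] == pytest.approx(v, rel=1e-9)
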