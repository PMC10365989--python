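"""Leontief systems: toy oracles, allocation, classification, conservation."""

import numpy as np
import pandas as pd
import pytest

from fpm import RunConfig
from fpm.errors import (
    ClassificationError,
    IndexingError,
    NonProductiveError,
    StructureError,
)
from fpm.mrio import (
    LeontiefSystem,
    SupplyUseSystem,
    classify_food,
    leontief_footprint,
    sut_to_coefficients,
)
from fpm.pipeline import mrio_footprint
from fpm.results import FootprintResult


def toy_system():
    return LeontiefSystem.from_coefficients(
        np.array([[0.1, 0.2], [0.3, 0.1]]),
        {"LF_crop_ha": [1.0, 2.0]},
        commodities=["s1", "s2"],
    )


class TestLeontiefAlgebra:
    def test_two_sector_solution(self):
        system = toy_system()
        x = system.solve(np.array([10.0, 20.0]))
        np.testing.assert_allclose(x, [52.0 / 3.0, 28.0], rtol=1e-12)
        total = float(system.extensions["LF_crop_ha"] @ x)
        assert total == pytest.approx(52.0 / 3.0 + 56.0, rel=1e-12)

    def test_direct_solve_matches_power_series(self):
        system = toy_system()
        y = np.array([3.0, 7.0])
        np.testing.assert_allclose(
            system.solve(y), system.solve(y, method="series", tolerance=1e-15), rtol=1e-10
        )

    def test_inverse_satisfies_identity(self):
        system = toy_system()
        n = system.n_nodes
        residual = system.leontief_inverse @ (np.eye(n) - system.coefficients) - np.eye(n)
        assert np.abs(residual).max() < 1e-8

    def test_zero_coefficients_give_direct_requirements_only(self):
        system = LeontiefSystem.from_coefficients(
            np.zeros((2, 2)), {"LF_crop_ha": [1.0, 2.0]}, commodities=["s1", "s2"]
        )
        demand = pd.DataFrame(
            [
                {"region": "R0", "commodity": "s1", "category": "hh", "value": 10.0},
                {"region": "R0", "commodity": "s2", "category": "hh", "value": 20.0},
            ]
        )
        result = leontief_footprint(system, demand)
        values = result.frame.set_index("product")["value"]
        assert values["s1"] == pytest.approx(10.0)
        assert values["s2"] == pytest.approx(40.0)

    def test_footprint_is_linear_in_demand(self):
        system = toy_system()
        demand = pd.DataFrame(
            [
                {"region": "R0", "commodity": "s1", "category": "hh", "value": 5.0},
                {"region": "R0", "commodity": "s2", "category": "hh", "value": 2.0},
            ]
        )
        single = leontief_footprint(system, demand).total()
        double = leontief_footprint(
            system, demand.assign(value=demand["value"] * 2)
        ).total()
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_nonproductive_matrix_rejected(self):
        with pytest.raises(NonProductiveError):
            LeontiefSystem.from_coefficients(
                np.array([[0.0, 1.1], [1.1, 0.0]]), {"LF_crop_ha": [1.0, 1.0]}
            )

    def test_unknown_demand_commodity_rejected(self):
        system = toy_system()
        demand = pd.DataFrame(
            [{"region": "R0", "commodity": "nope", "category": "hh", "value": 1.0}]
        )
        with pytest.raises(IndexingError):
            leontief_footprint(system, demand)


class TestSutConstruction:
    def _single_region_sut(self):
        supply = pd.DataFrame(
            [
                {"region": "R", "industry": "farm", "commodity": "wheat", "value": 100.0},
                {"region": "R", "industry": "mill", "commodity": "flour", "value": 40.0},
            ]
        )
        use = pd.DataFrame(
            [{"region": "R", "industry": "mill", "commodity": "wheat", "value": 50.0}]
        )
        demand = pd.DataFrame(
            [
                {"region": "R", "commodity": "wheat", "category": "hh", "value": 50.0},
                {"region": "R", "commodity": "flour", "category": "hh", "value": 40.0},
            ]
        )
        extensions = pd.DataFrame(
            [{"region": "R", "industry": "farm", "indicator": "LF_crop_ha", "value": 25.0}]
        )
        return SupplyUseSystem(supply, use, demand, extensions)

    def test_single_output_coefficients_are_use_per_output(self):
        sut = self._single_region_sut()
        system = sut_to_coefficients(sut, "mass")
        result = leontief_footprint(system, sut.final_demand)
        # all 100 t of wheat end in final use (50 direct + 50 via flour):
        # the whole 25 ha extension must be attributed
        assert result.total() == pytest.approx(25.0, rel=1e-10)
        flour = result.filter(product="flour").total()
        assert flour == pytest.approx(12.5, rel=1e-10)

    def test_multi_output_allocation_matches_hand_assembly(self):
        supply = pd.DataFrame(
            [
                {"region": "R", "industry": "farm", "commodity": "beans", "value": 100.0},
                {"region": "R", "industry": "crush", "commodity": "oil", "value": 18.0},
                {"region": "R", "industry": "crush", "commodity": "cake", "value": 79.0},
            ]
        )
        use = pd.DataFrame(
            [{"region": "R", "industry": "crush", "commodity": "beans", "value": 100.0}]
        )
        demand = pd.DataFrame(
            [
                {"region": "R", "commodity": "oil", "category": "hh", "value": 18.0},
                {"region": "R", "commodity": "cake", "category": "hh", "value": 79.0},
            ]
        )
        extensions = pd.DataFrame(
            [{"region": "R", "industry": "farm", "indicator": "LF_crop_ha", "value": 50.0}]
        )
        prices = pd.Series({"oil": 800.0, "cake": 350.0})
        sut = SupplyUseSystem(supply, use, demand, extensions, prices=prices)
        for mode, oil_share in (("mass", 18.0 / 97.0), ("value", 144.0 / 420.5)):
            system = sut_to_coefficients(sut, mode)
            result = leontief_footprint(system, demand)
            oil = result.filter(product="oil").total()
            assert oil == pytest.approx(50.0 * oil_share, rel=1e-10)
            assert result.total() == pytest.approx(50.0, rel=1e-10)

    def test_equal_prices_make_value_equal_mass_systems(self):
        supply = pd.DataFrame(
            [
                {"region": "R", "industry": "farm", "commodity": "beans", "value": 10.0},
                {"region": "R", "industry": "split", "commodity": "x", "value": 4.0},
                {"region": "R", "industry": "split", "commodity": "y", "value": 5.0},
            ]
        )
        use = pd.DataFrame(
            [{"region": "R", "industry": "split", "commodity": "beans", "value": 10.0}]
        )
        demand = pd.DataFrame(
            [{"region": "R", "commodity": "x", "category": "hh", "value": 4.0},
             {"region": "R", "commodity": "y", "category": "hh", "value": 5.0}]
        )
        extensions = pd.DataFrame(
            [{"region": "R", "industry": "farm", "indicator": "LF_crop_ha", "value": 7.0}]
        )
        prices = pd.Series({"x": 3.0, "y": 3.0})
        sut = SupplyUseSystem(supply, use, demand, extensions, prices=prices)
        a = sut_to_coefficients(sut, "mass").coefficients
        b = sut_to_coefficients(sut, "value").coefficients
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_industry_with_inputs_but_no_output_rejected(self):
        supply = pd.DataFrame(
            [{"region": "R", "industry": "farm", "commodity": "wheat", "value": 10.0}]
        )
        use = pd.DataFrame(
            [{"region": "R", "industry": "ghost", "commodity": "wheat", "value": 5.0}]
        )
        demand = pd.DataFrame(
            [{"region": "R", "commodity": "wheat", "category": "hh", "value": 5.0}]
        )
        extensions = pd.DataFrame(columns=["region", "industry", "indicator", "value"])
        with pytest.raises(StructureError, match="ghost"):
            sut_to_coefficients(
                SupplyUseSystem(supply, use, demand, extensions), "mass"
            )


class TestConservationOnWorlds:
    def test_footprint_sums_to_total_extension(self, dataset, default_config):
        """Every hectare and cubic metre in the extension table is attributed
        to exactly one final consumer."""
        result = mrio_footprint(dataset, default_config)
        totals = result.total(["indicator"])
        expected = dataset.extensions.groupby("indicator")["value"].sum()
        for indicator, value in expected.items():
            assert totals[indicator] == pytest.approx(value, rel=1e-8)


class TestFoodClassification:
    def _result(self):
        return FootprintResult(
            pd.DataFrame(
                [
                    {"model_variant": "M", "consumer": "A", "product": "wheat",
                     "origin": "A", "food_class": "unclassified",
                     "indicator": "LF_crop_ha", "value": 10.0},
                    {"model_variant": "M", "consumer": "A", "product": "hotel",
                     "origin": "A", "food_class": "unclassified",
                     "indicator": "LF_crop_ha", "value": 4.0},
                    {"model_variant": "M", "consumer": "A", "product": "hides",
                     "origin": "A", "food_class": "unclassified",
                     "indicator": "LF_crop_ha", "value": 2.0},
                ]
            )
        )

    def _classes(self):
        return pd.DataFrame(
            [
                {"commodity": "wheat", "class": "food_certain"},
                {"commodity": "hotel", "class": "food_possible"},
                {"commodity": "hides", "class": "nonfood"},
            ]
        )

    def test_min_max_difference_is_the_possible_food(self):
        result, classes = self._result(), self._classes()
        food_min = classify_food(result, classes, "min").filter(food_class="food").total()
        food_max = classify_food(result, classes, "max").filter(food_class="food").total()
        assert food_min == pytest.approx(10.0)
        assert food_max == pytest.approx(14.0)
        assert food_max - food_min == pytest.approx(4.0)

    def test_food_plus_nonfood_is_scenario_invariant(self):
        result, classes = self._result(), self._classes()
        totals = {
            scenario: classify_food(result, classes, scenario).total()
            for scenario in ("min", "max")
        }
        assert totals["min"] == pytest.approx(totals["max"])
        assert totals["min"] == pytest.approx(16.0)

    def test_min_food_never_exceeds_max_food_cellwise(self):
        result, classes = self._result(), self._classes()
        keys = ["consumer", "product", "indicator"]
        food_min = classify_food(result, classes, "min").filter(food_class="food").total(keys)
        food_max = classify_food(result, classes, "max").filter(food_class="food").total(keys)
        joined = food_min.to_frame("lo").join(food_max.to_frame("hi"), how="outer").fillna(0.0)
        assert (joined["lo"] <= joined["hi"] + 1e-12).all()

    def test_unclassified_product_rejected(self):
        with pytest.raises(ClassificationError, match="hides"):
            classify_food(self._result(), self._classes().iloc[:2], "min")

    def test_all_food_certain_makes_food_equal_total(self):
        result = self._result()
        classes = self._classes().assign(**{"class": "food_certain"})
        for scenario in ("min", "max"):
            out = classify_food(result, classes, scenario)
            assert out.filter(food_class="food").total() == pytest.approx(out.total())
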