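"""Cooking-energy models: specific heat dispatch, per-appliance and per-method
energies, and the cooking-stage CO2 composition."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recipefootprint.cooking_energy import (
    J_PER_WH,
    MethodEnergy,
    cooking_footprint,
    gas_method_energy,
    ingredient_heating_energy,
    microwave_energy,
    oven_energy,
    post_boil_holding_energy,
    recipe_uses_rice,
    rice_cooker_energy,
    specific_heat,
    water_boil_energy,
)
from recipefootprint.data_model import (
    Appliance,
    CookingStep,
    EnergyConstants,
    GasMethod,
    MassFractions,
)

from conftest import gas_step, make_recipe

WATER = MassFractions(moisture=1.0, protein=0.0, carbohydrate=0.0, fat=0.0, ash=0.0)


class TestSpecificHeat:
    def test_pure_water_low_fat_formula(self):
        # the two-term formula collapses to the water coefficient, 4187 J/(kg K)
        assert specific_heat(WATER) * 1000 == pytest.approx(4187.0)

    def test_high_fat_three_term_formula(self):
        m = MassFractions(moisture=0.5, protein=0.1, carbohydrate=0.1, fat=0.3, ash=0.0)
        expected = (1.0 * 0.5 + 0.5 * 0.3 + 0.33 * 0.2) * 4187 / 1000
        assert specific_heat(m) == pytest.approx(expected)
        assert specific_heat(m) == pytest.approx(2.998, abs=5e-4)

    def test_high_ash_five_term_formula(self):
        m = MassFractions(moisture=0.6, protein=0.1, carbohydrate=0.1, fat=0.05, ash=0.15)
        expected = (2512.2 + 154.9 + 142.4 + 83.75 + 125.55) / 1000  # term-by-term hand sum
        assert specific_heat(m) == pytest.approx(expected)

    def test_five_term_agrees_with_two_term_at_pure_water(self):
        ashless = specific_heat(WATER)
        five_term = (4187 * 1.0) / 1000
        assert ashless == pytest.approx(five_term)

    def test_override_wins(self):
        assert specific_heat(WATER, override=3.5) == 3.5

    def test_unknown_composition_is_error(self):
        zero = MassFractions(moisture=0, protein=0, carbohydrate=0, fat=0, ash=0)
        with pytest.raises(ValueError, match="composition unknown"):
            specific_heat(zero)

    def test_branch_dispatch_order(self):
        # ash >= 0.1 takes the five-term formula even when fat is low
        ashy = MassFractions(moisture=0.7, protein=0.05, carbohydrate=0.1, fat=0.0, ash=0.15)
        expected = (4187 * 0.7 + 1424 * 0.1 + 1549 * 0.05 + 837 * 0.15) / 1000
        assert specific_heat(ashy) == pytest.approx(expected)


class TestApplianceEnergies:
    def test_microwave_examples(self, constants):
        assert microwave_energy(500, 300, constants) == pytest.approx(150000 / 0.71)
        assert microwave_energy(600, 60, constants) == pytest.approx(36000 / 0.71)
        assert microwave_energy(900, 0, constants) == 0.0

    def test_oven_is_power_times_time(self):
        assert oven_energy(1000, 600) == 600000.0
        assert oven_energy(1000, 0) == 0.0
        assert oven_energy(1000, 1200) == 2 * oven_energy(1000, 600)

    def test_rice_cooker_cycle(self, constants):
        assert rice_cooker_energy(constants) == pytest.approx(183.8)
        assert rice_cooker_energy(EnergyConstants(rice_warm_hours=0)) == pytest.approx(156.0)
        assert rice_cooker_energy(EnergyConstants(rice_warm_hours=1)) == pytest.approx(169.9)

    def test_water_boil_examples(self, constants):
        assert water_boil_energy(1000, constants) == pytest.approx(336000 / 0.37)
        assert water_boil_energy(0, constants) == 0.0
        assert water_boil_energy(500, constants) == pytest.approx(
            water_boil_energy(1000, constants) / 2
        )

    def test_post_boil_holding_examples(self, constants):
        assert post_boil_holding_energy(10, constants) == pytest.approx(423900 / 0.42)
        assert post_boil_holding_energy(0, constants) == 0.0
        assert post_boil_holding_energy(15, constants) == pytest.approx(
            1.5 * post_boil_holding_energy(10, constants)
        )


class TestIngredientHeating:
    def test_worked_example(self, small_table, constants):
        # 300 g of the plain fixture: c = (0.8 + 0.2*0.2) * 4.187 = 3.51708
        recipe = make_recipe([("plain", 300.0)])
        energy = ingredient_heating_energy(recipe, small_table, 80.0, 0.42, 1.0)
        assert energy == pytest.approx(300 * 3.51708 * 80 / 0.42)

    def test_empty_quantities_give_zero(self, small_table, constants):
        recipe = make_recipe([("plain", 0.0)])
        assert ingredient_heating_energy(recipe, small_table, 80.0, 0.42) == 0.0

    def test_pan_coverage_inflates_demand(self, small_table):
        recipe = make_recipe([("plain", 300.0)])
        full = ingredient_heating_energy(recipe, small_table, 100.0, 0.37, 1.0)
        partial = ingredient_heating_energy(recipe, small_table, 100.0, 0.37, 0.75)
        assert partial == pytest.approx(full * 4 / 3)


class TestGasMethods:
    def test_boil_sums_three_components(self, small_table, constants):
        recipe = make_recipe([("plain", 500.0)], steps=[gas_step(GasMethod.BOIL)])
        result = gas_method_energy(GasMethod.BOIL, recipe, small_table, constants)
        c_plain = 3.51708
        eq6 = 2500 * 4.20 * 80 / 0.37
        eq7 = 0.06 * 314 * 2250 * 10 / 0.42
        eq8 = 500 * c_plain * 80 / 0.42
        assert result.components["boil_water"] == pytest.approx(eq6)
        assert result.components["hold"] == pytest.approx(eq7)
        assert result.components["heat_food"] == pytest.approx(eq8)
        assert result.energy == pytest.approx(eq6 + eq7 + eq8)

    def test_fry_oil_only(self, small_table, constants):
        recipe = make_recipe([("plain", 0.0)])
        step = gas_step(GasMethod.FRY, oil_grams=200.0)
        result = gas_method_energy(GasMethod.FRY, recipe, small_table, constants, step)
        assert result.components["heat_oil"] == pytest.approx(200 * 1.96 * 160 / 0.37)
        assert result.components["heat_food"] == 0.0

    def test_steam_water_mass_is_pot_geometry(self, small_table, constants):
        # 60% of a 314 cm^2 x 15 cm pot -> 2826 g of water, recipe-independent
        for grams in (10.0, 500.0):
            recipe = make_recipe([("plain", grams)], cook_time=30.0)
            result = gas_method_energy(GasMethod.STEAM, recipe, small_table, constants)
            assert result.components["boil_water"] == pytest.approx(
                water_boil_energy(2826.0, constants)
            )

    def test_simmer_uses_step_water_and_time_fraction(self, small_table, constants):
        step = gas_step(GasMethod.SIMMER, water_grams=600.0)
        recipe = make_recipe([("plain", 200.0)], cook_time=30.0, steps=[step])
        result = gas_method_energy(GasMethod.SIMMER, recipe, small_table, constants, step)
        assert result.components["boil_water"] == pytest.approx(water_boil_energy(600.0, constants))
        assert result.components["hold"] == pytest.approx(
            post_boil_holding_energy(20.0, constants)  # 2/3 of 30 min
        )

    def test_post_boil_override(self, small_table, constants):
        step = gas_step(GasMethod.SIMMER, water_grams=600.0, post_boil_minutes=5.0)
        recipe = make_recipe([("plain", 200.0)], cook_time=30.0, steps=[step])
        result = gas_method_energy(GasMethod.SIMMER, recipe, small_table, constants, step)
        assert result.components["hold"] == pytest.approx(post_boil_holding_energy(5.0, constants))

    def test_stir_fry_uses_heating_efficiency_and_coverage(self, small_table, constants):
        recipe = make_recipe([("plain", 300.0)])
        result = gas_method_energy(GasMethod.STIR_FRY, recipe, small_table, constants)
        assert result.energy == pytest.approx(300 * 3.51708 * 100 / (0.37 * 0.75))

    def test_missing_required_parameters(self, small_table, constants):
        recipe = make_recipe([("plain", 100.0)])
        with pytest.raises(ValueError, match="water_grams"):
            gas_method_energy(GasMethod.SIMMER, recipe, small_table, constants)
        with pytest.raises(ValueError, match="oil_grams"):
            gas_method_energy(GasMethod.FRY, recipe, small_table, constants)

    @given(grams=st.floats(min_value=0.0, max_value=2000.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_in_mass(self, small_table, constants, grams):
        lighter = make_recipe([("plain", grams)])
        heavier = make_recipe([("plain", grams + 50.0)])
        for method in (GasMethod.BOIL, GasMethod.STIR_FRY):
            low = gas_method_energy(method, lighter, small_table, constants)
            high = gas_method_energy(method, heavier, small_table, constants)
            assert high.energy >= low.energy >= 0.0


class TestCookingFootprint:
    def test_single_gas_method_1mj(self, small_table, constants, factors):
        # stir-fry sized to exactly 1 MJ: Q c dK/(eta alpha) = 1e6
        q = 1e6 * 0.37 * 0.75 / (3.51708 * 100)
        recipe = make_recipe([("plain", q)], steps=[gas_step(GasMethod.STIR_FRY)])
        result = cooking_footprint(recipe, small_table, constants, factors)
        assert result.gas_mean_mj == pytest.approx(1.0)
        assert result.total_g == pytest.approx(49.9)

    def test_electric_only_1kwh(self, small_table, constants, factors):
        # microwave sized to exactly 1 kWh of electricity
        duration = 3.6e6 * 0.71 / 1000.0
        step = CookingStep(appliance=Appliance.MICROWAVE, power_watts=1000.0,
                           duration_seconds=duration)
        recipe = make_recipe([("plain", 100.0)], steps=[step])
        result = cooking_footprint(recipe, small_table, constants, factors)
        assert result.electric_kwh == pytest.approx(1.0)
        assert result.total_g == pytest.approx(441.0)

    def test_gas_methods_averaged_then_electric_added(self, small_table, constants, factors):
        # two gas methods of 1 and 3 MJ plus 0.1 kWh -> 2*49.9 + 0.1*441
        q_stir = 1e6 * 0.37 * 0.75 / (3.51708 * 100)
        recipe = make_recipe(
            [("plain", q_stir)],
            steps=[
                gas_step(GasMethod.STIR_FRY),
                gas_step(GasMethod.FRY, oil_grams=1.0),
                CookingStep(appliance=Appliance.MICROWAVE, power_watts=1000.0,
                            duration_seconds=0.1 * 3.6e6 * 0.71 / 1000.0),
            ],
        )
        fry = cooking_footprint(recipe, small_table, constants, factors)
        mj = [m.energy / 1e6 for m in fry.gas_method_energies.values()]
        expected = sum(mj) / len(mj) * 49.9 + 0.1 * 441.0
        assert fry.total_g == pytest.approx(expected)

    def test_duplicate_methods_counted_once(self, small_table, constants, factors):
        base = make_recipe([("plain", 300.0)], steps=[gas_step(GasMethod.STIR_FRY)])
        doubled = make_recipe(
            [("plain", 300.0)],
            steps=[gas_step(GasMethod.STIR_FRY), gas_step(GasMethod.STIR_FRY)],
        )
        one = cooking_footprint(base, small_table, constants, factors)
        two = cooking_footprint(doubled, small_table, constants, factors)
        assert two.total_g == pytest.approx(one.total_g)

    def test_rice_ingredient_adds_cooker_cycle(self, small_table, constants, factors):
        recipe = make_recipe([("rice", 300.0)])
        result = cooking_footprint(recipe, small_table, constants, factors)
        assert result.rice_cooker_added
        assert result.electric_kwh == pytest.approx(0.1838)
        assert result.total_g == pytest.approx(0.1838 * 441.0)
        assert recipe_uses_rice(recipe, small_table)

    def test_no_steps_no_rice_is_zero_with_warning(self, small_table, constants, factors):
        recipe = make_recipe([("cabbage", 100.0)])
        with pytest.warns(UserWarning, match="no cooking steps"):
            result = cooking_footprint(recipe, small_table, constants, factors)
        assert result.total_g == 0.0
        assert result.warning is not None

    def test_oven_power_falls_back_to_config(self, small_table, factors):
        constants = EnergyConstants(oven_power_watts=1500.0)
        step = CookingStep(appliance=Appliance.OVEN, duration_seconds=600.0)
        recipe = make_recipe([("plain", 100.0)], steps=[step])
        result = cooking_footprint(recipe, small_table, constants, factors)
        assert result.electric_kwh == pytest.approx(1500.0 * 600.0 / J_PER_WH / 1000.0)


def test_component_breakdown_must_sum():
    with pytest.raises(ValueError, match="components sum"):
        MethodEnergy("bad", 10.0, "gas", {"a": 3.0, "b": 3.0})


def test_wh_joule_conversion_pins_units():
    assert J_PER_WH == 3600.0
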