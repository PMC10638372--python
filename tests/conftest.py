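"""Shared fixtures: a small hand-built ingredient world and generated fixture
files, so every engine is exercised both in memory and through the file
interfaces."""

from __future__ import annotations

import pytest

from recipefootprint.data_model import (
    Appliance,
    CookingStep,
    EmissionFactors,
    EnergyConstants,
    GasMethod,
    IngredientLine,
    IngredientRecord,
    LossRateEntry,
    LossRateTable,
    MassFractions,
    QuantityUnit,
    RawQuantity,
    Recipe,
)
from recipefootprint.footprint_pipeline import ReferenceTables
from recipefootprint.synthetic_fixtures import FixtureSpec, write_fixture_set


def make_record(
    iid: str,
    *,
    waste: float = 0.0,
    price: float = 0.5,  # JPY per g
    intensity: float = 4.0,  # g CO2e per JPY
    category: str = "vegetables",
    moisture: float = 0.8,
    protein: float = 0.1,
    carbohydrate: float = 0.1,
    fat: float = 0.0,
    ash: float = 0.0,
    override: float | None = None,
    density: dict[str, float] | None = None,
    bounds: tuple[float, float] | None = None,
    name: str | None = None,
) -> IngredientRecord:
    return IngredientRecord(
        ingredient_id=iid,
        canonical_name=name or iid,
        nutrient_density=density or {},
        waste_rate=waste,
        mass_fractions=MassFractions(
            moisture=moisture, protein=protein, carbohydrate=carbohydrate, fat=fat, ash=ash
        ),
        specific_heat_override=override,
        unit_price=price,
        price_bounds=bounds,
        emission_intensity=intensity,
        loss_category=category,
    )


def make_recipe(
    lines: list[tuple[str, float]],
    *,
    servings: int = 1,
    steps: list[CookingStep] | None = None,
    cook_time: float = 30.0,
    recipe_id: str = "r1",
) -> Recipe:
    """A recipe with already-resolved gram quantities."""
    return Recipe(
        recipe_id=recipe_id,
        name=recipe_id,
        servings=servings,
        cook_time_minutes=cook_time,
        lines=[
            IngredientLine(
                ingredient_id=iid,
                raw_quantity=RawQuantity(value=grams, unit=QuantityUnit.GRAM),
                resolved_grams=grams,
            )
            for iid, grams in lines
        ],
        steps=steps or [],
    )


def gas_step(method: GasMethod, **kwargs) -> CookingStep:
    return CookingStep(appliance=Appliance.GAS_STOVE, method=method, **kwargs)


@pytest.fixture(scope="session")
def constants() -> EnergyConstants:
    return EnergyConstants()


@pytest.fixture(scope="session")
def factors() -> EmissionFactors:
    return EmissionFactors()


@pytest.fixture(scope="session")
def loss_table() -> LossRateTable:
    return LossRateTable(
        entries={
            "vegetables": LossRateEntry(rate=0.088),
            "meat": LossRateEntry(rate=0.022),
            "grains": LossRateEntry(rate=0.030),
            "beans": LossRateEntry(rate=0.040),
            "oils": LossRateEntry(rate=0.005),
        }
    )


@pytest.fixture(scope="session")
def small_table() -> dict[str, IngredientRecord]:
    """Hand-built mini ingredient world used by the worked examples."""
    return {
        "cabbage": make_record(
            "cabbage", waste=0.1, price=0.2, intensity=3.0, category="vegetables",
            density={"iron_mg": 0.5, "vitamin_c_mg": 0.4, "energy_kcal": 0.23},
            bounds=(0.16, 0.24),
        ),
        "pork": make_record(
            "pork", waste=0.0, price=1.5, intensity=8.0, category="meat:pork",
            moisture=0.65, protein=0.2, carbohydrate=0.0, fat=0.15,
            density={"protein_g": 0.2, "energy_kcal": 2.4}, bounds=(1.2, 1.8),
        ),
        "tofu": make_record(
            "tofu", waste=0.0, price=0.3, intensity=2.0, category="beans",
            moisture=0.85, protein=0.08, carbohydrate=0.05,
            density={"protein_g": 0.07}, bounds=(0.24, 0.36),
        ),
        "rice": make_record(
            "rice", waste=0.0, price=0.4, intensity=2.5, category="grains:rice",
            moisture=0.6, protein=0.05, carbohydrate=0.35,
            density={"carbohydrate_g": 0.37, "energy_kcal": 1.68}, bounds=(0.32, 0.48),
        ),
        "oil": make_record(
            "oil", waste=0.0, price=0.35, intensity=1.8, category="oils",
            moisture=0.0, protein=0.0, carbohydrate=0.0, fat=0.999,
            density={"fat_g": 1.0, "energy_kcal": 9.0}, bounds=(0.28, 0.42),
        ),
        # moisture 0.8, solids 0.2, low fat -> c = (0.8 + 0.2*0.2)*4.187 = 3.51708 J/(g K)
        "plain": make_record("plain", bounds=(0.4, 0.6)),
    }


@pytest.fixture(scope="session")
def small_tables(small_table, loss_table) -> ReferenceTables:
    return ReferenceTables(ingredients=small_table, loss_rates=loss_table)


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """A generated fixture set on disk (seed 1)."""
    out = tmp_path_factory.mktemp("fixtures")
    return write_fixture_set(FixtureSpec(seed=1), out)


@pytest.fixture(scope="session")
def fixture_tables(fixture_paths) -> ReferenceTables:
    return ReferenceTables.from_files(
        fixture_paths["ingredients"], fixture_paths["loss_rates"], fixture_paths["piece_mass"]
    )
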