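"""Deterministic synthetic fixtures: ingredient tables, loss-rate tables,
price sources, piece-mass tables and recipe sets.

These emulate the *structure* of the real reference data — a food-composition
table (nutrient densities per 100 g, waste rates, proximate composition), a
food-loss survey (category loss rates), an expenditure survey (unit prices)
and EEIO emission intensities — without claiming statistical realism.  Every
engine is testable offline with them.  Draws come from one seeded NumPy
generator; the same seed yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    NUTRIENTS,
    Appliance,
    CookingStep,
    EmissionFactors,
    EnergyConstants,
    GasMethod,
    IngredientLine,
    IngredientRecord,
    LossRateEntry,
    LossRateTable,
    QuantityUnit,
    RawQuantity,
    Recipe,
    ingredient_table_columns,
)

__all__ = [
    "FixtureSpec",
    "paper_constants_fixture",
    "reference_loss_rates",
    "generate_ingredient_table",
    "generate_recipes",
    "generate_price_sources",
    "write_fixture_set",
    "recipe_to_json",
]

MIN_INGREDIENTS = 6


@dataclass(frozen=True)
class FixtureSpec:
    """Shape parameters of a synthetic fixture set.

    Defaults give a small but structurally complete world: a dozen
    ingredients spanning every specific-heat branch and dish class, realistic
    Japanese-retail price and intensity magnitudes, and a recipe set covering
    every appliance and gas method.
    """

    seed: int = 0
    n_ingredients: int = 12
    n_extra_recipes: int = 4
    price_per_100g_range: tuple[float, float] = (20.0, 400.0)
    price_bound_halfwidth: float = 0.2  # relative to the point price
    intensity_range: tuple[float, float] = (1.0, 8.0)  # g-CO2e per JPY
    waste_rate_range: tuple[float, float] = (0.0, 0.35)
    lines_per_recipe: tuple[int, int] = (2, 5)
    grams_per_line_range: tuple[float, float] = (20.0, 400.0)
    servings_range: tuple[int, int] = (1, 4)
    cook_time_minutes_range: tuple[float, float] = (10.0, 45.0)


def paper_constants_fixture() -> tuple[EnergyConstants, EmissionFactors, LossRateTable]:
    """The published physical constants, emission factors, and a loss-rate
    excerpt (vegetables 8.8%, meat 2.2%, with survey components)."""
    excerpt = LossRateTable(
        entries={
            "vegetables": LossRateEntry(
                rate=0.088, w_left=5.0, w_direct=3.0, w_excessive=0.8, u_food=100.0
            ),
            "meat": LossRateEntry(
                rate=0.022, w_left=1.2, w_direct=0.6, w_excessive=0.4, u_food=100.0
            ),
        }
    )
    return EnergyConstants(), EmissionFactors(), excerpt


# Category -> food-loss rate for the synthetic loss table.  Vegetables and
# meat carry the published survey rates; the remaining categories are fixed
# plausible magnitudes (leftover-prone fresh produce loses more than shelf-
# stable staples), chosen once for the fixture world.
_LOSS_RATES: dict[str, tuple[float, tuple[float, float, float, float] | None]] = {
    "vegetables": (0.088, (5.0, 3.0, 0.8, 100.0)),
    "meat": (0.022, (1.2, 0.6, 0.4, 100.0)),
    "grains": (0.030, (2.0, 0.8, 0.2, 100.0)),
    "seafood": (0.025, None),
    "eggs": (0.020, None),
    "mushrooms": (0.060, None),
    "beans": (0.040, None),
    "seasonings": (0.010, None),
    "oils": (0.005, None),
    "dairy": (0.010, None),
}


def reference_loss_rates() -> LossRateTable:
    """The full synthetic loss-rate table (published anchors plus fixture
    categories)."""
    return LossRateTable(
        entries={
            cat: LossRateEntry(
                rate=rate,
                w_left=comp[0] if comp else None,
                w_direct=comp[1] if comp else None,
                w_excessive=comp[2] if comp else None,
                u_food=comp[3] if comp else None,
            )
            for cat, (rate, comp) in _LOSS_RATES.items()
        }
    )


# (loss_category, price_item, typical moisture) for mandatory branch-coverage
# ingredients, then a pool for the rest.
_MANDATORY = [
    ("grains:rice", "rice", 0.60),
    ("meat:pork", "pork", 0.65),
    ("vegetables", "fresh_vegetables", 0.92),
    ("seasonings", "seasonings", 0.45),  # generated with ash >= 0.1
    ("oils", "cooking_oil", 0.02),  # generated with fat > 0.01
    ("vegetables", "fresh_vegetables", 0.90),  # carries a handbook override
]
_POOL = [
    ("vegetables", "fresh_vegetables", 0.92),
    ("grains", "noodles", 0.35),
    ("eggs", "eggs", 0.76),
    ("mushrooms", "mushrooms", 0.90),
    ("beans", "tofu", 0.85),
    ("seafood", "fresh_fish", 0.75),
    ("dairy", "milk", 0.87),
    ("meat:chicken", "chicken", 0.70),
]

# Per-100 g density ranges for the synthetic composition table, in the fixed
# nutrient units (kcal / g / mg / ug per 100 g).
_NUTRIENT_RANGES: dict[str, tuple[float, float]] = {
    "energy_kcal": (15.0, 400.0),
    "carbohydrate_g": (0.0, 60.0),
    "protein_g": (0.5, 25.0),
    "fat_g": (0.0, 30.0),
    "vitamin_a_ug": (0.0, 300.0),
    "vitamin_c_mg": (0.0, 60.0),
    "vitamin_e_mg": (0.0, 3.0),
    "zinc_mg": (0.0, 3.0),
    "calcium_mg": (0.0, 150.0),
    "iron_mg": (0.0, 3.0),
    "potassium_mg": (30.0, 500.0),
    "magnesium_mg": (2.0, 60.0),
    "folic_acid_ug": (0.0, 120.0),
    "dietary_fiber_g": (0.0, 5.0),
    "saturated_fat_g": (0.0, 10.0),
    "cholesterol_mg": (0.0, 100.0),
    "salt_equivalent_g": (0.0, 4.0),
}


def _mass_fractions(rng: np.random.Generator, moisture: float, *, high_ash: bool,
                    high_fat: bool) -> tuple[float, float, float, float, float]:
    """Draw a proximate composition summing to <= 1 around a target moisture."""
    m_w = float(np.clip(moisture + rng.uniform(-0.05, 0.05), 0.0, 0.97))
    remainder = 1.0 - m_w
    if high_ash:
        m_ash = max(0.1, 0.4 * remainder)
    else:
        m_ash = float(rng.uniform(0.0, 0.05 * remainder))
    rest = remainder - m_ash
    if high_fat:
        m_fat = max(0.02, float(rng.uniform(0.3, 0.9)) * rest)
    else:
        m_fat = float(rng.uniform(0.0, 0.3)) * rest
    m_fat = min(m_fat, rest)
    split = float(rng.uniform(0.2, 0.8))
    m_protein = (rest - m_fat) * split
    m_carb = (rest - m_fat) * (1.0 - split)
    return m_w, m_protein, m_carb, m_fat, m_ash


def generate_ingredient_table(spec: FixtureSpec) -> pd.DataFrame:
    """Synthetic ingredient reference table in the documented CSV layout.

    Guarantees at least one rice-class, meat-class and vegetable-class
    ingredient, one high-ash (>= 0.1), one high-fat (> 0.01) composition and
    one specific-heat override, so every dispatcher branch is reachable.
    """
    if spec.n_ingredients < MIN_INGREDIENTS:
        raise ValueError(
            f"need at least {MIN_INGREDIENTS} ingredients to cover all branches, "
            f"got {spec.n_ingredients}"
        )
    rng = np.random.default_rng(spec.seed)
    roles = list(_MANDATORY)
    while len(roles) < spec.n_ingredients:
        roles.append(_POOL[int(rng.integers(len(_POOL)))])

    rows = []
    for idx, (category, price_item, moisture) in enumerate(roles):
        high_ash = idx == 3
        high_fat = idx == 4
        m_w, m_p, m_c, m_f, m_m = _mass_fractions(
            rng, moisture, high_ash=high_ash, high_fat=high_fat
        )
        price = float(rng.uniform(*spec.price_per_100g_range))
        row: dict = {
            "ingredient_id": f"ing{idx:03d}",
            "canonical_name": f"{category.replace(':', ' ')} {idx:03d}",
            "waste_rate": round(float(rng.uniform(*spec.waste_rate_range)), 3),
            "m_moisture": round(m_w, 4),
            "m_protein": round(m_p, 4),
            "m_carbohydrate": round(m_c, 4),
            "m_fat": round(m_f, 4),
            "m_ash": round(m_m, 4),
            "specific_heat_override": 3.5 if idx == 5 else "",
            "unit_price_jpy_per_100g": round(price, 2),
            "price_min": round(price * (1.0 - spec.price_bound_halfwidth), 2),
            "price_max": round(price * (1.0 + spec.price_bound_halfwidth), 2),
            "emission_intensity_g_per_jpy": round(float(rng.uniform(*spec.intensity_range)), 3),
            "loss_category": category,
            "price_item": price_item,
        }
        for nutrient, (lo, hi) in _NUTRIENT_RANGES.items():
            row[f"{nutrient}_per_100g"] = round(float(rng.uniform(lo, hi)), 2)
        rows.append(row)
    return pd.DataFrame(rows, columns=ingredient_table_columns())


def _line(rng: np.random.Generator, spec: FixtureSpec, ingredient_id: str) -> IngredientLine:
    grams = round(float(rng.uniform(*spec.grams_per_line_range)), 1)
    return IngredientLine(
        ingredient_id=ingredient_id,
        raw_quantity=RawQuantity(value=grams, unit=QuantityUnit.GRAM),
    )


def _pick_lines(
    rng: np.random.Generator, spec: FixtureSpec, table: pd.DataFrame, *, with_rice: bool = False
) -> list[IngredientLine]:
    """Pick ingredient lines with at most one meat/seafood class per recipe."""
    ids = list(table["ingredient_id"])
    categories = dict(zip(table["ingredient_id"], table["loss_category"]))
    n = int(rng.integers(spec.lines_per_recipe[0], spec.lines_per_recipe[1] + 1))
    chosen: list[str] = []
    meat_class = None
    if with_rice:
        rice = [i for i in ids if categories[i] == "grains:rice"]
        chosen.append(rice[0])
    classifiable = ("meat", "seafood", "grains", "eggs", "vegetables", "mushrooms", "beans")
    while len(chosen) < n:
        cand = ids[int(rng.integers(len(ids)))]
        if cand in chosen:
            continue
        prefix = categories[cand].split(":", 1)[0]
        if prefix in ("meat", "seafood"):
            if meat_class is not None and meat_class != categories[cand]:
                continue
            meat_class = categories[cand]
        chosen.append(cand)
    # dish categorization needs at least one class-bearing ingredient
    if not any(categories[c].split(":", 1)[0] in classifiable for c in chosen):
        veg = [i for i in ids if categories[i] == "vegetables"]
        chosen[-1] = veg[0]
    return [_line(rng, spec, i) for i in chosen]


def generate_recipes(spec: FixtureSpec, table: pd.DataFrame) -> list[Recipe]:
    """Synthetic recipe set covering every appliance and gas method at least
    once, plus one vague-quantity line, one count-quantity line, and one
    rice-implied recipe with no explicit rice-cooker step."""
    if len(table) == 0:
        raise ValueError("ingredient table is empty")
    rng = np.random.default_rng(spec.seed + 1)
    recipes: list[Recipe] = []

    def new_recipe(rid: str, lines: list[IngredientLine], steps: list[CookingStep]) -> Recipe:
        return Recipe(
            recipe_id=rid,
            name=f"fixture dish {rid}",
            servings=int(rng.integers(spec.servings_range[0], spec.servings_range[1] + 1)),
            cook_time_minutes=round(float(rng.uniform(*spec.cook_time_minutes_range)), 1),
            lines=lines,
            steps=steps,
        )

    method_steps = {
        "simmer": CookingStep(
            appliance=Appliance.GAS_STOVE, method=GasMethod.SIMMER,
            water_grams=round(float(rng.uniform(200, 1000)), 1),
        ),
        "boil": CookingStep(appliance=Appliance.GAS_STOVE, method=GasMethod.BOIL),
        "steam": CookingStep(appliance=Appliance.GAS_STOVE, method=GasMethod.STEAM),
        "stir_fry": CookingStep(appliance=Appliance.GAS_STOVE, method=GasMethod.STIR_FRY),
        "fry": CookingStep(
            appliance=Appliance.GAS_STOVE, method=GasMethod.FRY,
            oil_grams=round(float(rng.uniform(100, 400)), 1),
        ),
        "microwave": CookingStep(
            appliance=Appliance.MICROWAVE, power_watts=500.0, duration_seconds=300.0
        ),
        "oven": CookingStep(
            appliance=Appliance.OVEN, power_watts=1000.0, duration_seconds=600.0
        ),
        "rice_cooker": CookingStep(appliance=Appliance.RICE_COOKER),
    }
    for label, step in method_steps.items():
        recipes.append(
            new_recipe(
                f"r_{label}",
                _pick_lines(rng, spec, table, with_rice=label == "rice_cooker"),
                [step],
            )
        )

    # rice implied by ingredient, no explicit rice-cooker step
    recipes.append(
        new_recipe(
            "r_rice_implied",
            _pick_lines(rng, spec, table, with_rice=True),
            [method_steps["stir_fry"]],
        )
    )
    # vague and count quantities on a vegetable-class ingredient
    veg_id = table.loc[table["loss_category"] == "vegetables", "ingredient_id"].iloc[0]
    special = [
        IngredientLine(
            ingredient_id=veg_id, raw_quantity=RawQuantity(value=0.0, unit=QuantityUnit.VAGUE)
        ),
        IngredientLine(
            ingredient_id=veg_id, raw_quantity=RawQuantity(value=2.0, unit=QuantityUnit.COUNT)
        ),
    ] + _pick_lines(rng, spec, table)
    recipes.append(new_recipe("r_special_quantities", special, [method_steps["boil"]]))

    gas_labels = ["simmer", "boil", "steam", "stir_fry", "fry"]
    for k in range(spec.n_extra_recipes):
        label = gas_labels[int(rng.integers(len(gas_labels)))]
        steps = [method_steps[label]]
        if rng.random() < 0.5:
            steps.append(method_steps["microwave"])
        recipes.append(new_recipe(f"r_extra_{k}", _pick_lines(rng, spec, table), steps))
    return recipes


def generate_price_sources(spec: FixtureSpec) -> pd.DataFrame:
    """Price-source table exercising all four resolution paths: survey-priced
    items, retail-only items, category-average items, and substitutions."""
    rng = np.random.default_rng(spec.seed + 2)

    def price() -> float:
        return round(float(rng.uniform(*spec.price_per_100g_range)), 1)

    rows = [
        # path 1: household survey
        {"item": "rice", "survey_price_jpy_per_100g": price(), "category": "grains"},
        {"item": "noodles", "survey_price_jpy_per_100g": price(), "category": "grains"},
        {"item": "pork", "survey_price_jpy_per_100g": price(),
         "retail_price_jpy_per_100g": price(), "category": "meat"},
        {"item": "chicken", "survey_price_jpy_per_100g": price(),
         "retail_price_jpy_per_100g": price(), "category": "meat"},
        {"item": "fresh_vegetables", "survey_price_jpy_per_100g": price(),
         "category": "vegetables"},
        {"item": "eggs", "survey_price_jpy_per_100g": price(), "category": "eggs"},
        {"item": "tofu", "survey_price_jpy_per_100g": price(), "category": "beans"},
        {"item": "milk", "survey_price_jpy_per_100g": price(), "category": "dairy"},
        {"item": "seasonings", "survey_price_jpy_per_100g": price(), "category": "seasonings"},
        {"item": "cooking_oil", "survey_price_jpy_per_100g": price(), "category": "oils"},
        # path 2: retail only, needs the correction coefficient
        {"item": "fresh_fish", "retail_price_jpy_per_100g": price(), "category": "seafood"},
        {"item": "mushrooms", "retail_price_jpy_per_100g": price(), "category": "mushrooms"},
        # path 3: category average over grains
        {"item": "other_grains", "category": "grains"},
        # path 4: substitution
        {"item": "shumai_like", "category": "prepared", "substitution_target": "pork"},
    ]
    columns = ["item", "survey_price_jpy_per_100g", "retail_price_jpy_per_100g",
               "category", "substitution_target"]
    return pd.DataFrame(rows, columns=columns)


def recipe_to_json(recipe: Recipe) -> dict:
    """Serialize a recipe to the documented JSON schema."""
    return {
        "recipe_id": recipe.recipe_id,
        "name": recipe.name,
        "servings": recipe.servings,
        "cook_time_minutes": recipe.cook_time_minutes,
        "ingredients": [
            {
                "ingredient_id": line.ingredient_id,
                "quantity": {
                    "value": line.raw_quantity.value,
                    "unit": line.raw_quantity.unit.value,
                },
            }
            for line in recipe.lines
        ],
        "steps": [
            {
                key: (value.value if hasattr(value, "value") else value)
                for key, value in step.model_dump(exclude_none=True).items()
            }
            for step in recipe.steps
        ],
        **({"cuisine": recipe.cuisine} if recipe.cuisine else {}),
    }


def write_fixture_set(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Emit a complete fixture set through the standard file interfaces:
    ingredients.csv, loss_rates.csv, price_sources.csv, piece_mass.csv,
    recipes.json and constants.yaml.  Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = generate_ingredient_table(spec)
    recipes = generate_recipes(spec, table)
    prices = generate_price_sources(spec)

    paths = {name: out / fname for name, fname in [
        ("ingredients", "ingredients.csv"),
        ("loss_rates", "loss_rates.csv"),
        ("price_sources", "price_sources.csv"),
        ("piece_mass", "piece_mass.csv"),
        ("recipes", "recipes.json"),
        ("constants", "constants.yaml"),
        ("factors", "factors.yaml"),
    ]}
    table.to_csv(paths["ingredients"], index=False)
    loss = reference_loss_rates()
    pd.DataFrame(
        [
            {"loss_category": cat, "rate": e.rate, "w_left": e.w_left,
             "w_direct": e.w_direct, "w_excessive": e.w_excessive, "u_food": e.u_food}
            for cat, e in loss.entries.items()
        ]
    ).to_csv(paths["loss_rates"], index=False)
    prices.to_csv(paths["price_sources"], index=False)
    # piece masses for every ingredient so count quantities always resolve
    pd.DataFrame(
        {"ingredient_id": table["ingredient_id"], "grams_per_piece": 50.0}
    ).to_csv(paths["piece_mass"], index=False)
    with open(paths["recipes"], "w") as fh:
        json.dump({"recipes": [recipe_to_json(r) for r in recipes]}, fh, indent=1, sort_keys=True)
    constants, factors, _ = paper_constants_fixture()
    with open(paths["constants"], "w") as fh:
        yaml.safe_dump(constants.model_dump(), fh, sort_keys=True)
    with open(paths["factors"], "w") as fh:
        yaml.safe_dump(factors.model_dump(), fh, sort_keys=True)
    return paths
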