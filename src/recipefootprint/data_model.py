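"""Domain types, file readers/writers, quantity resolution, and dish categorization.

Everything downstream (nutrition, pricing, cooking energy, disposal) consumes the
validated records defined here.  The two on-disk interfaces are

* an ingredient reference CSV, one row per ingredient, carrying nutrient densities
  per 100 g of edible portion (the food-composition-table convention), the inedible
  waste rate ``D_i``, proximate mass fractions, a unit price per 100 g, an EEIO
  emission intensity in g-CO2e per JPY, and a food-loss category tag;
* recipe JSON files with ingredient lines (value + unit) and structured cooking
  steps (appliance, method, power/duration/water/oil parameters).

Nutrient densities and prices are stored *per gram* internally; the readers divide
per-100 g columns by 100 on ingest.
"""

from __future__ import annotations

import enum
import json
import math
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "NUTRIENTS",
    "MassFractions",
    "IngredientRecord",
    "QuantityUnit",
    "RawQuantity",
    "IngredientLine",
    "Appliance",
    "GasMethod",
    "CookingStep",
    "Recipe",
    "EnergyConstants",
    "EmissionFactors",
    "LossRateTable",
    "LossRateEntry",
    "load_ingredient_table",
    "load_loss_rate_table",
    "load_piece_mass_table",
    "load_recipes",
    "resolve_quantity",
    "resolve_recipe",
    "dish_class_of",
    "categorize_dish",
    "method_from_keyword",
    "write_results",
    "read_results",
    "MEAT_CLASSES",
    "PLANT_CLASS_ORDER",
]

# The fixed 17-nutrient set, name -> unit of the *per-serving* amount.  Densities
# are stored in <unit>/g of edible portion.
NUTRIENTS: dict[str, str] = {
    "energy_kcal": "kcal",
    "carbohydrate_g": "g",
    "protein_g": "g",
    "fat_g": "g",
    "vitamin_a_ug": "ug",
    "vitamin_c_mg": "mg",
    "vitamin_e_mg": "mg",
    "zinc_mg": "mg",
    "calcium_mg": "mg",
    "iron_mg": "mg",
    "potassium_mg": "mg",
    "magnesium_mg": "mg",
    "folic_acid_ug": "ug",
    "dietary_fiber_g": "g",
    "saturated_fat_g": "g",
    "cholesterol_mg": "mg",
    "salt_equivalent_g": "g",
}

MASS_FRACTION_SUM_TOL = 0.02


class MassFractions(BaseModel):
    """Proximate composition of an ingredient as mass fractions of fresh weight.

    moisture/protein/carbohydrate/fat/ash; used only by the specific-heat
    estimator.  Fractions need not sum exactly to 1 (rounding in composition
    tables); a 2% overshoot is tolerated.
    """

    model_config = ConfigDict(frozen=True)

    moisture: float = Field(ge=0.0, le=1.0)
    protein: float = Field(ge=0.0, le=1.0)
    carbohydrate: float = Field(ge=0.0, le=1.0)
    fat: float = Field(ge=0.0, le=1.0)
    ash: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check_sum(self) -> "MassFractions":
        total = self.moisture + self.protein + self.carbohydrate + self.fat + self.ash
        if total > 1.0 + MASS_FRACTION_SUM_TOL:
            raise ValueError(f"mass fractions sum to {total:.4f} > 1 + {MASS_FRACTION_SUM_TOL}")
        return self

    @property
    def solids(self) -> float:
        """Protein + carbohydrate, treated jointly in the low-fat heat model."""
        return self.protein + self.carbohydrate


class IngredientRecord(BaseModel):
    """One row of the ingredient reference table.

    ``nutrient_density`` maps nutrient name -> amount per gram of *edible*
    portion; nutrients absent from the table are treated as 0 (unmeasured or
    trace).  ``unit_price`` is JPY per gram of purchased (whole) weight,
    ``emission_intensity`` is g-CO2e per JPY spent.

    ``loss_category`` is a hierarchical tag ``<class>[:<subclass>]`` — e.g.
    ``vegetables``, ``meat:pork``, ``grains:rice`` — serving both as the
    food-loss-rate key (with prefix fallback) and as the dish-classification
    class.
    """

    model_config = ConfigDict(frozen=True)

    ingredient_id: str
    canonical_name: str
    nutrient_density: dict[str, float] = Field(default_factory=dict)
    waste_rate: float = Field(ge=0.0, le=1.0)
    mass_fractions: MassFractions
    specific_heat_override: Optional[float] = Field(default=None, gt=0.0)
    unit_price: float = Field(ge=0.0)
    price_bounds: Optional[tuple[float, float]] = None
    emission_intensity: float = Field(ge=0.0)
    loss_category: str
    price_item: Optional[str] = None

    @field_validator("nutrient_density")
    @classmethod
    def _nonnegative_densities(cls, v: dict[str, float]) -> dict[str, float]:
        for name, dens in v.items():
            if name not in NUTRIENTS:
                raise ValueError(f"unknown nutrient {name!r}")
            if dens < 0:
                raise ValueError(f"nutrient density {name} = {dens} < 0")
        return v

    @model_validator(mode="after")
    def _check_bounds(self) -> "IngredientRecord":
        if self.price_bounds is not None:
            lo, hi = self.price_bounds
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid price bounds ({lo}, {hi})")
        return self

    def density(self, nutrient: str) -> float:
        """Per-gram density of ``nutrient``; 0 when unmeasured."""
        return self.nutrient_density.get(nutrient, 0.0)


class QuantityUnit(str, enum.Enum):
    GRAM = "g"
    MILLILITER = "ml"
    COUNT = "count"
    VAGUE = "vague"


class RawQuantity(BaseModel):
    """A recipe quantity as written: a value and a unit tag.

    ``vague`` covers "appropriate amount" / "a bit" / "a pinch" expressions and
    resolves to 0 g; ``count`` needs a piece-mass table entry.
    """

    model_config = ConfigDict(frozen=True)

    value: float = Field(default=0.0, ge=0.0)
    unit: QuantityUnit = QuantityUnit.GRAM


class IngredientLine(BaseModel):
    ingredient_id: str
    raw_quantity: RawQuantity
    resolved_grams: Optional[float] = Field(default=None, ge=0.0)


class Appliance(str, enum.Enum):
    MICROWAVE = "microwave"
    OVEN = "oven"
    RICE_COOKER = "rice_cooker"
    GAS_STOVE = "gas_stove"


class GasMethod(str, enum.Enum):
    SIMMER = "simmer"
    BOIL = "boil"
    STEAM = "steam"
    STIR_FRY = "stir_fry"
    FRY = "fry"


class CookingStep(BaseModel):
    """One structured cooking step.

    Electric appliances (microwave, oven) carry power and duration; the gas
    stove carries a method plus method-specific parameters (water for simmer,
    oil for fry); the rice cooker needs no parameters (its energy is a fixed
    cycle).  ``post_boil_minutes`` overrides the default post-boil holding time.
    """

    model_config = ConfigDict(frozen=True)

    appliance: Appliance
    method: Optional[GasMethod] = None
    power_watts: Optional[float] = Field(default=None, gt=0.0)
    duration_seconds: Optional[float] = Field(default=None, gt=0.0)
    water_grams: Optional[float] = Field(default=None, ge=0.0)
    oil_grams: Optional[float] = Field(default=None, ge=0.0)
    post_boil_minutes: Optional[float] = Field(default=None, ge=0.0)

    @model_validator(mode="after")
    def _check_required(self) -> "CookingStep":
        if self.appliance is Appliance.MICROWAVE:
            if self.power_watts is None or self.duration_seconds is None:
                raise ValueError("microwave step requires power_watts and duration_seconds")
        if self.appliance is Appliance.OVEN and self.duration_seconds is None:
            raise ValueError("oven step requires duration_seconds")
        if (self.method is not None) != (self.appliance is Appliance.GAS_STOVE):
            raise ValueError("method is required iff appliance is gas_stove")
        return self


class Recipe(BaseModel):
    recipe_id: str
    name: str = ""
    servings: int = Field(ge=1)
    cook_time_minutes: float = Field(default=0.0, ge=0.0)
    lines: list[IngredientLine] = Field(min_length=1)
    steps: list[CookingStep] = Field(default_factory=list)
    cuisine: Optional[str] = None

    @property
    def resolved(self) -> bool:
        return all(line.resolved_grams is not None for line in self.lines)

    def total_grams(self) -> float:
        if not self.resolved:
            raise ValueError(f"recipe {self.recipe_id}: quantities not resolved")
        return sum(line.resolved_grams for line in self.lines)  # type: ignore[misc]


class EnergyConstants(BaseModel):
    """Physical constants of the cooking-energy models.

    Defaults are the published measurement-based values: appliance conversion
    efficiencies, water/oil specific heats, the latent heat of vaporization,
    temperature rises per method, the pot evaporation rate and geometry, and
    the rice-cooker cycle.  ``oven_power_watts`` is a fallback for oven steps
    that do not state a power; it is a fixture default (a typical oven-range
    element), not a published constant.
    """

    model_config = ConfigDict(frozen=True)

    eta_microwave: float = Field(default=0.71, gt=0.0, le=1.0)
    eta_heating: float = Field(default=0.37, gt=0.0, le=1.0)
    eta_after_boil: float = Field(default=0.42, gt=0.0, le=1.0)
    c_water: float = Field(default=4.20, gt=0.0)  # J/(g K)
    latent_heat_water: float = Field(default=2250.0, gt=0.0)  # J/g
    c_oil: float = Field(default=1.96, gt=0.0)  # J/(g K)
    dk_boil: float = Field(default=80.0, gt=0.0)  # K, room -> boiling
    dk_stir_fry: float = Field(default=100.0, gt=0.0)  # K, food before/after stir-fry
    dk_oil: float = Field(default=160.0, gt=0.0)  # K, room -> frying oil temp
    dk_deep_fry: float = Field(default=130.0, gt=0.0)  # K, food before/after frying
    evaporation_rate: float = Field(default=0.06, gt=0.0)  # g/(min cm^2)
    pot_bottom_area_cm2: float = Field(default=314.0, gt=0.0)
    pan_coverage: float = Field(default=0.75, gt=0.0, le=1.0)  # alpha
    pot_depth_cm: float = Field(default=15.0, gt=0.0)
    steam_fill_fraction: float = Field(default=0.6, gt=0.0, le=1.0)
    boil_water_multiple: float = Field(default=5.0, gt=0.0)
    boil_hold_minutes: float = Field(default=10.0, ge=0.0)
    simmer_hold_time_fraction: float = Field(default=2.0 / 3.0, gt=0.0, le=1.0)
    rice_cook_wh: float = Field(default=156.0, ge=0.0)
    rice_warm_wh_per_hour: float = Field(default=13.9, ge=0.0)
    rice_warm_hours: float = Field(default=2.0, ge=0.0)
    oven_power_watts: float = Field(default=1000.0, gt=0.0)
    # Food-heating efficiency in simmer/boil/steam is the after-boil value as
    # printed; set to eta_heating to model food heated from room temperature.
    food_heating_eta_boil_methods: Optional[float] = Field(default=None, gt=0.0, le=1.0)

    def eta_food_boil_methods(self) -> float:
        return (
            self.food_heating_eta_boil_methods
            if self.food_heating_eta_boil_methods is not None
            else self.eta_after_boil
        )


class EmissionFactors(BaseModel):
    """CO2 coefficients: grid electricity, city gas, and waste incineration.

    The per-gram disposal factor must equal the per-stage breakdown
    (collection, incineration, transport, landfill; kg CO2 per 1000 kg of raw
    garbage) summed and divided by 1000.
    """

    model_config = ConfigDict(frozen=True)

    electricity_g_per_kwh: float = Field(default=441.0, ge=0.0)
    city_gas_g_per_mj: float = Field(default=49.9, ge=0.0)
    disposal_g_per_g_waste: float = Field(default=0.1064, ge=0.0)
    disposal_stage_breakdown: dict[str, float] = Field(
        default_factory=lambda: {
            "collection": 24.0,
            "incineration": 73.0,
            "transport": 3.7,
            "landfill": 5.7,
        }
    )

    @model_validator(mode="after")
    def _check_consistency(self) -> "EmissionFactors":
        total = sum(self.disposal_stage_breakdown.values()) / 1000.0
        if abs(total - self.disposal_g_per_g_waste) > 1e-9:
            raise ValueError(
                f"disposal factor {self.disposal_g_per_g_waste} != stage sum/1000 = {total}"
            )
        return self


class LossRateEntry(BaseModel):
    """Food-loss rate for one category, optionally with its survey components
    (leftover, direct-waste and excessive-removal amounts over food used)."""

    model_config = ConfigDict(frozen=True)

    rate: float = Field(ge=0.0, lt=1.0)
    w_left: Optional[float] = Field(default=None, ge=0.0)
    w_direct: Optional[float] = Field(default=None, ge=0.0)
    w_excessive: Optional[float] = Field(default=None, ge=0.0)
    u_food: Optional[float] = Field(default=None, gt=0.0)


class LossRateTable(BaseModel):
    """Mapping loss-category -> food-loss waste rate W (fraction of the edible
    portion discarded as leftovers + direct waste + excessive removal).

    Lookup falls back from ``class:subclass`` to ``class`` so fine ingredient
    tags (``grains:rice``) share their category rate.
    """

    entries: dict[str, LossRateEntry]

    def rate(self, category: str) -> float:
        entry = self.entries.get(category)
        if entry is None and ":" in category:
            entry = self.entries.get(category.split(":", 1)[0])
        if entry is None:
            raise KeyError(f"no food-loss rate for category {category!r}")
        return entry.rate


# ---------------------------------------------------------------------------
# Readers / writers

_INGREDIENT_SCALAR_COLUMNS = [
    "ingredient_id",
    "canonical_name",
    "waste_rate",
    "m_moisture",
    "m_protein",
    "m_carbohydrate",
    "m_fat",
    "m_ash",
    "specific_heat_override",
    "unit_price_jpy_per_100g",
    "price_min",
    "price_max",
    "emission_intensity_g_per_jpy",
    "loss_category",
    "price_item",
]


def ingredient_table_columns() -> list[str]:
    """Documented CSV header: scalars plus one ``<nutrient>_per_100g`` column each."""
    cols = ["ingredient_id", "canonical_name"]
    cols += [f"{n}_per_100g" for n in NUTRIENTS]
    cols += _INGREDIENT_SCALAR_COLUMNS[2:]
    return cols


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def load_ingredient_table(path: str | Path) -> dict[str, IngredientRecord]:
    """Read the ingredient reference CSV into validated records keyed by id.

    Per-100 g nutrient and price columns are divided by 100 on ingest; a
    missing nutrient column (or empty cell) becomes density 0.  Duplicate
    ingredient ids and invariant violations raise ``ValueError`` naming the
    offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"ingredient_id": str})
    required = {"ingredient_id", "canonical_name", "waste_rate", "m_moisture", "m_protein",
                "m_carbohydrate", "m_fat", "m_ash", "unit_price_jpy_per_100g",
                "emission_intensity_g_per_jpy", "loss_category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")

    records: dict[str, IngredientRecord] = {}
    for idx, row in df.iterrows():
        iid = str(row["ingredient_id"])
        if iid in records:
            raise ValueError(f"{path} row {idx}: duplicate ingredient_id {iid!r}")
        density: dict[str, float] = {}
        for nutrient in NUTRIENTS:
            col = f"{nutrient}_per_100g"
            val = _opt(row[col]) if col in df.columns else None
            if val is not None:
                density[nutrient] = val / 100.0
        try:
            fractions = MassFractions(
                moisture=float(row["m_moisture"]),
                protein=float(row["m_protein"]),
                carbohydrate=float(row["m_carbohydrate"]),
                fat=float(row["m_fat"]),
                ash=float(row["m_ash"]),
            )
            pmin = _opt(row.get("price_min"))
            pmax = _opt(row.get("price_max"))
            bounds = (pmin / 100.0, pmax / 100.0) if pmin is not None and pmax is not None else None
            price_item = row.get("price_item")
            records[iid] = IngredientRecord(
                ingredient_id=iid,
                canonical_name=str(row["canonical_name"]),
                nutrient_density=density,
                waste_rate=float(row["waste_rate"]),
                mass_fractions=fractions,
                specific_heat_override=_opt(row.get("specific_heat_override")),
                unit_price=float(row["unit_price_jpy_per_100g"]) / 100.0,
                price_bounds=bounds,
                emission_intensity=float(row["emission_intensity_g_per_jpy"]),
                loss_category=str(row["loss_category"]),
                price_item=None if pd.isna(price_item) else str(price_item),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} row {idx} (ingredient {iid!r}): {exc}") from exc
    return records


def load_loss_rate_table(path: str | Path) -> LossRateTable:
    """Read the loss-rate CSV: loss_category plus either component amounts
    (w_left, w_direct, w_excessive, u_food) or a precomputed ``rate`` column."""
    df = pd.read_csv(path)
    entries: dict[str, LossRateEntry] = {}
    for idx, row in df.iterrows():
        cat = str(row["loss_category"])
        components = [_opt(row.get(c)) for c in ("w_left", "w_direct", "w_excessive", "u_food")]
        if all(c is not None for c in components):
            w_left, w_direct, w_excessive, u_food = components
            rate = (w_left + w_direct + w_excessive) / u_food  # type: ignore[operator]
        else:
            rate = _opt(row.get("rate"))
            w_left = w_direct = w_excessive = u_food = None
            if rate is None:
                raise ValueError(f"{path} row {idx} ({cat!r}): neither components nor rate given")
        entries[cat] = LossRateEntry(
            rate=rate, w_left=w_left, w_direct=w_direct, w_excessive=w_excessive, u_food=u_food
        )
    return LossRateTable(entries=entries)


def load_piece_mass_table(path: str | Path) -> dict[str, float]:
    """Read the piece-mass CSV (ingredient_id, grams_per_piece)."""
    df = pd.read_csv(path, dtype={"ingredient_id": str})
    return {str(r["ingredient_id"]): float(r["grams_per_piece"]) for _, r in df.iterrows()}


def load_recipes(path: str | Path) -> list[Recipe]:
    """Read recipe JSON: either a list of recipe objects or {"recipes": [...]}.

    Each recipe object mirrors the documented schema: ``ingredients`` entries
    carry ``{ingredient_id, quantity: {value, unit}}`` and ``steps`` carry the
    structured cooking-step fields.
    """
    with open(path) as fh:
        payload = json.load(fh)
    raw_recipes = payload["recipes"] if isinstance(payload, dict) else payload
    recipes = []
    for raw in raw_recipes:
        lines = [
            IngredientLine(
                ingredient_id=str(ing["ingredient_id"]),
                raw_quantity=RawQuantity(**ing["quantity"]),
            )
            for ing in raw["ingredients"]
        ]
        steps = [CookingStep(**s) for s in raw.get("steps", [])]
        recipes.append(
            Recipe(
                recipe_id=str(raw["recipe_id"]),
                name=raw.get("name", ""),
                servings=int(raw["servings"]),
                cook_time_minutes=float(raw.get("cook_time_minutes", 0.0)),
                lines=lines,
                steps=steps,
                cuisine=raw.get("cuisine"),
            )
        )
    return recipes


# ---------------------------------------------------------------------------
# Quantity resolution

def resolve_quantity(
    raw_quantity: RawQuantity,
    piece_mass_table: Mapping[str, float] | None = None,
    ingredient_id: str | None = None,
) -> float:
    """Convert a raw recipe quantity to grams.

    Milliliters convert 1:1 to grams (water-like densities assumed for
    condiments and liquids); vague amounts ("a pinch" etc.) are exactly 0 g;
    count units multiply by the per-piece mass from the piece-mass table.
    """
    unit = raw_quantity.unit
    if unit in (QuantityUnit.GRAM, QuantityUnit.MILLILITER):
        return float(raw_quantity.value)
    if unit is QuantityUnit.VAGUE:
        return 0.0
    if unit is QuantityUnit.COUNT:
        if not piece_mass_table or ingredient_id not in piece_mass_table:
            raise KeyError(
                f"no piece-mass entry for count-quantity ingredient {ingredient_id!r}"
            )
        return float(raw_quantity.value) * piece_mass_table[ingredient_id]
    raise ValueError(f"unrecognized quantity unit {unit!r}")


def resolve_recipe(recipe: Recipe, piece_mass_table: Mapping[str, float] | None = None) -> Recipe:
    """Return a copy of ``recipe`` with every line's ``resolved_grams`` set."""
    lines = [
        line.model_copy(
            update={
                "resolved_grams": resolve_quantity(
                    line.raw_quantity, piece_mass_table, line.ingredient_id
                )
            }
        )
        for line in recipe.lines
    ]
    return recipe.model_copy(update={"lines": lines})


# ---------------------------------------------------------------------------
# Dish categorization

MEAT_CLASSES = (
    "beef",
    "pork",
    "chicken",
    "minced_meat",
    "other_fresh_meat",
    "processed_meat",
    "seafood",
)
PLANT_CLASS_ORDER = ("grains", "eggs", "vegetables", "mushrooms", "beans")


def dish_class_of(record: IngredientRecord) -> Optional[str]:
    """Dish class of one ingredient, derived from its ``loss_category`` tag.

    ``meat:<sub>`` maps to the meat subclass (beef, pork, ...), ``seafood``
    (any subtag) to seafood, plant-class prefixes to themselves; anything else
    (oils, seasonings, dairy, beverages) does not drive categorization.
    """
    prefix, _, sub = record.loss_category.partition(":")
    if prefix == "meat":
        return sub if sub in MEAT_CLASSES else "other_fresh_meat"
    if prefix == "seafood":
        return "seafood"
    if prefix in PLANT_CLASS_ORDER:
        return prefix
    return None


def categorize_dish(recipe: Recipe, ingredient_table: Mapping[str, IngredientRecord]) -> str:
    """Classify a dish by its dominant ingredient class.

    A meat/seafood ingredient determines the class outright (two distinct
    meat/seafood classes in one recipe is an error — the classification scheme
    assumes they do not co-occur); otherwise the plant class with the largest
    total resolved mass wins, ties broken by the fixed class order grains →
    eggs → vegetables → mushrooms → beans.
    """
    if not recipe.resolved:
        raise ValueError(f"recipe {recipe.recipe_id}: resolve quantities before categorizing")
    meat_found: set[str] = set()
    plant_mass: dict[str, float] = {}
    for line in recipe.lines:
        record = ingredient_table.get(line.ingredient_id)
        if record is None:
            raise KeyError(f"recipe {recipe.recipe_id}: unknown ingredient {line.ingredient_id!r}")
        cls = dish_class_of(record)
        if cls is None:
            continue
        if cls in MEAT_CLASSES:
            meat_found.add(cls)
        else:
            plant_mass[cls] = plant_mass.get(cls, 0.0) + (line.resolved_grams or 0.0)
    if len(meat_found) > 1:
        raise ValueError(
            f"recipe {recipe.recipe_id}: multiple meat/seafood classes {sorted(meat_found)}"
        )
    if meat_found:
        return meat_found.pop()
    if not plant_mass:
        raise ValueError(f"recipe {recipe.recipe_id}: no classifiable ingredient")
    best = max(plant_mass, key=lambda c: (plant_mass[c], -PLANT_CLASS_ORDER.index(c)))
    return best


# Convenience mapping from free-text direction keywords to structured methods.
# The engine contract is the structured CookingStep; this is plumbing only.
_METHOD_KEYWORDS = {
    "simmer": GasMethod.SIMMER,
    "stew": GasMethod.SIMMER,
    "boil": GasMethod.BOIL,
    "blanch": GasMethod.BOIL,
    "steam": GasMethod.STEAM,
    "stir-fry": GasMethod.STIR_FRY,
    "stir fry": GasMethod.STIR_FRY,
    "saute": GasMethod.STIR_FRY,
    "grill": GasMethod.STIR_FRY,
    "pan-fry": GasMethod.STIR_FRY,
    "deep-fry": GasMethod.FRY,
    "deep fry": GasMethod.FRY,
    "fry": GasMethod.FRY,
}


def method_from_keyword(text: str) -> Optional[GasMethod]:
    """Map a direction keyword ('boil', 'grill', ...) to a gas method, longest
    match first; returns None when nothing matches."""
    lowered = text.strip().lower()
    for key in sorted(_METHOD_KEYWORDS, key=len, reverse=True):
        if key in lowered:
            return _METHOD_KEYWORDS[key]
    return None


# ---------------------------------------------------------------------------
# Results I/O

RESULT_SCALAR_FIELDS = [
    "recipe_id",
    "category",
    "servings",
    "ghg_production_g",
    "ghg_cooking_g",
    "ghg_disposal_g",
    "ghg_foodloss_production_g",
    "ghg_total_per_serving_g",
    "price_per_serving_jpy",
    "disposal_amount_g",
]


def write_results(results: Sequence, path: str | Path, format: str = "csv") -> None:
    """Write footprint results (one record per recipe) to CSV or JSON.

    Full float precision is kept so a write/read round-trip preserves values
    to well below 1e-9; presentation rounding is the caller's concern.
    """
    rows = []
    for res in results:
        row = {field: getattr(res, field) for field in RESULT_SCALAR_FIELDS}
        for nutrient in NUTRIENTS:
            row[f"nutrient_{nutrient}"] = res.nutrients.amounts.get(nutrient, 0.0)
        rows.append(row)
    path = Path(path)
    columns = RESULT_SCALAR_FIELDS + [f"nutrient_{n}" for n in NUTRIENTS]
    if format == "csv":
        df = pd.DataFrame(rows, columns=columns)
        df.to_csv(path, index=False, float_format="%.17g")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
    else:
        raise ValueError(f"unknown results format {format!r}")


def read_results(path: str | Path, format: str = "csv") -> pd.DataFrame:
    """Read a results file back into a DataFrame (matching ``write_results``)."""
    if format == "csv":
        return pd.read_csv(path, dtype={"recipe_id": str})
    if format == "json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    raise ValueError(f"unknown results format {format!r}")
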