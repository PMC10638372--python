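"""Whole-recipe evaluation: assemble the three-stage carbon footprint,
per-serving price and nutrients, batch processing, and the price-bounds
uncertainty analysis.

The production-and-sales footprint uses EEIO emission intensities on the money
spent per ingredient:

    E_p = sum_i Q_i P_i I_i        [g CO2e]

and the per-serving footprint of a dish combines the three stages:

    E = (E_p + E_c + E_d) / S

E_p covers *all* purchased ingredients, food-loss share included; the
loss-attributed part E_p,foodloss is reported alongside, not subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import yaml

from . import waste_disposal
from .cooking_energy import CookingFootprint, cooking_footprint
from .data_model import (
    EmissionFactors,
    EnergyConstants,
    IngredientRecord,
    LossRateTable,
    Recipe,
    categorize_dish,
    load_ingredient_table,
    load_loss_rate_table,
    load_piece_mass_table,
    load_recipes,
    resolve_recipe,
    write_results,
)
from .nutrition import NutrientVector, nutrients_per_serving
from .pricing import price_per_serving

__all__ = [
    "ReferenceTables",
    "PriceUncertainty",
    "FootprintResult",
    "BatchSummary",
    "load_constants",
    "load_factors",
    "production_footprint",
    "price_uncertainty",
    "evaluate_recipe",
    "run_batch",
]


@dataclass(frozen=True)
class ReferenceTables:
    """Everything an evaluation needs besides the recipe itself."""

    ingredients: dict[str, IngredientRecord]
    loss_rates: LossRateTable
    piece_mass: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_files(
        cls,
        ingredients_path: str | Path,
        loss_rates_path: str | Path,
        piece_mass_path: str | Path | None = None,
    ) -> "ReferenceTables":
        return cls(
            ingredients=load_ingredient_table(ingredients_path),
            loss_rates=load_loss_rate_table(loss_rates_path),
            piece_mass=load_piece_mass_table(piece_mass_path) if piece_mass_path else {},
        )


def load_constants(path: str | Path | None = None) -> EnergyConstants:
    """Energy constants, optionally overridden by a YAML key-value file whose
    keys mirror the ``EnergyConstants`` field names."""
    if path is None:
        return EnergyConstants()
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    return EnergyConstants(**overrides)


def load_factors(path: str | Path | None = None) -> EmissionFactors:
    """Emission factors, optionally overridden by a YAML key-value file."""
    if path is None:
        return EmissionFactors()
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    return EmissionFactors(**overrides)


def production_footprint(
    recipe: Recipe,
    ingredient_table: Mapping[str, IngredientRecord],
    price_scale: float = 1.0,
    price_override: Optional[Mapping[str, float]] = None,
) -> float:
    """Production-and-sales CO2 (g): spend per ingredient (full purchased
    weight, inedible parts included) times its emission intensity.

    ``price_override`` substitutes per-gram prices for selected ingredients
    (used by the uncertainty analysis); ``price_scale`` rescales all prices.
    """
    if not recipe.resolved:
        raise ValueError(f"recipe {recipe.recipe_id}: quantities not resolved")
    total = 0.0
    for line in recipe.lines:
        record = ingredient_table.get(line.ingredient_id)
        if record is None:
            raise KeyError(
                f"recipe {recipe.recipe_id}: no emission intensity for "
                f"ingredient {line.ingredient_id!r}"
            )
        price = (
            price_override[line.ingredient_id]
            if price_override and line.ingredient_id in price_override
            else record.unit_price
        )
        total += line.resolved_grams * price * price_scale * record.emission_intensity  # type: ignore[operator]
    return total


@dataclass(frozen=True)
class PriceUncertainty:
    """Production-footprint range induced by per-ingredient price bounds, and
    the per-serving total range it implies (cooking and disposal stages do not
    depend on price)."""

    ep_min_g: float
    ep_max_g: float
    e_min_per_serving_g: float
    e_max_per_serving_g: float
    ep_relative_half_range: float
    e_relative_half_range: float


def price_uncertainty(
    recipe: Recipe,
    tables: ReferenceTables,
    ec_g: float,
    ed_g: float,
    ep_point_g: float,
) -> PriceUncertainty:
    """Recompute the production footprint at every ingredient's minimum and
    maximum unit price and propagate to the per-serving total.

    Requires price bounds for every line; relative half-ranges are against the
    point-price results.
    """
    missing = [
        line.ingredient_id
        for line in recipe.lines
        if (rec := tables.ingredients.get(line.ingredient_id)) is None or rec.price_bounds is None
    ]
    if missing:
        raise ValueError(
            f"recipe {recipe.recipe_id}: no price bounds for ingredients {missing}"
        )
    lo = {i: tables.ingredients[i].price_bounds[0] for i in (l.ingredient_id for l in recipe.lines)}  # type: ignore[index]
    hi = {i: tables.ingredients[i].price_bounds[1] for i in (l.ingredient_id for l in recipe.lines)}  # type: ignore[index]
    ep_min = production_footprint(recipe, tables.ingredients, price_override=lo)
    ep_max = production_footprint(recipe, tables.ingredients, price_override=hi)
    e_point = (ep_point_g + ec_g + ed_g) / recipe.servings
    e_min = (ep_min + ec_g + ed_g) / recipe.servings
    e_max = (ep_max + ec_g + ed_g) / recipe.servings
    ep_half = (ep_max - ep_min) / 2.0
    e_half = (e_max - e_min) / 2.0
    return PriceUncertainty(
        ep_min_g=ep_min,
        ep_max_g=ep_max,
        e_min_per_serving_g=e_min,
        e_max_per_serving_g=e_max,
        ep_relative_half_range=ep_half / ep_point_g if ep_point_g > 0 else 0.0,
        e_relative_half_range=e_half / e_point if e_point > 0 else 0.0,
    )


@dataclass(frozen=True)
class FootprintResult:
    """Per-recipe outputs: the three stage footprints, the food-loss share of
    production, the per-serving total, price, nutrients and waste mass."""

    recipe_id: str
    category: str
    servings: int
    ghg_production_g: float
    ghg_cooking_g: float
    ghg_disposal_g: float
    ghg_foodloss_production_g: float
    ghg_total_per_serving_g: float
    price_per_serving_jpy: float
    disposal_amount_g: float
    nutrients: NutrientVector
    cooking: Optional[CookingFootprint] = None
    uncertainty: Optional[PriceUncertainty] = None

    def __post_init__(self) -> None:
        components = (
            self.ghg_production_g + self.ghg_cooking_g + self.ghg_disposal_g
        ) / self.servings
        if abs(components - self.ghg_total_per_serving_g) > 1e-9 * max(1.0, components):
            raise ValueError("per-serving total does not reconstruct from its stages")


def evaluate_recipe(
    recipe: Recipe,
    tables: ReferenceTables,
    constants: EnergyConstants | None = None,
    factors: EmissionFactors | None = None,
    with_uncertainty: bool = False,
) -> FootprintResult:
    """Full evaluation of one recipe: nutrients, price, three-stage footprint,
    waste mass, dish category, and (optionally) the price-bounds uncertainty.

    Quantities must be resolved (or resolvable via the piece-mass table); each
    failing sub-engine raises an error naming its stage.
    """
    constants = constants or EnergyConstants()
    factors = factors or EmissionFactors()
    if not recipe.resolved:
        recipe = resolve_recipe(recipe, tables.piece_mass)

    def _stage(name, fn, *args):
        try:
            return fn(*args)
        except (KeyError, ValueError) as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    nutrients = _stage("nutrition", nutrients_per_serving, recipe, tables.ingredients)
    price = _stage("pricing", price_per_serving, recipe, tables.ingredients)
    ep = _stage("production", production_footprint, recipe, tables.ingredients)
    cooking = _stage("cooking", cooking_footprint, recipe, tables.ingredients, constants, factors)
    waste = _stage("disposal", waste_disposal.disposal_mass, recipe, tables.ingredients, tables.loss_rates)
    ed = waste_disposal.disposal_footprint(waste, factors)
    ep_foodloss = _stage(
        "disposal", waste_disposal.foodloss_production_footprint,
        recipe, tables.ingredients, tables.loss_rates,
    )
    category = _stage("categorization", categorize_dish, recipe, tables.ingredients)
    uncertainty = (
        _stage("uncertainty", price_uncertainty, recipe, tables, cooking.total_g, ed, ep)
        if with_uncertainty
        else None
    )
    return FootprintResult(
        recipe_id=recipe.recipe_id,
        category=category,
        servings=recipe.servings,
        ghg_production_g=ep,
        ghg_cooking_g=cooking.total_g,
        ghg_disposal_g=ed,
        ghg_foodloss_production_g=ep_foodloss,
        ghg_total_per_serving_g=(ep + cooking.total_g + ed) / recipe.servings,
        price_per_serving_jpy=price,
        disposal_amount_g=waste.total_g,
        nutrients=nutrients,
        cooking=cooking,
        uncertainty=uncertainty,
    )


@dataclass
class BatchSummary:
    """Outcome of a batch run: per-recipe results, recorded failures, and mean
    per-serving footprint by dish category."""

    results: list[FootprintResult]
    failures: list[dict]
    mean_e_by_category: dict[str, float]

    @property
    def count(self) -> int:
        return len(self.results)


def run_batch(
    recipes_path: str | Path,
    tables: ReferenceTables,
    out_path: str | Path | None = None,
    constants: EnergyConstants | None = None,
    factors: EmissionFactors | None = None,
    with_uncertainty: bool = False,
    strict: bool = False,
    format: str = "csv",
) -> BatchSummary:
    """Evaluate every recipe in a file, write results, and summarize.

    Per-recipe failures are collected rather than fatal (a pipeline should not
    die on one bad row) unless ``strict`` is set, in which case the first
    failure propagates.  Deterministic given identical inputs.
    """
    recipes = load_recipes(recipes_path)
    results: list[FootprintResult] = []
    failures: list[dict] = []
    for recipe in recipes:
        try:
            results.append(
                evaluate_recipe(
                    recipe, tables, constants, factors, with_uncertainty=with_uncertainty
                )
            )
        except (KeyError, ValueError) as exc:
            if strict:
                raise
            failures.append({"recipe_id": recipe.recipe_id, "error": str(exc)})
    if out_path is not None:
        write_results(results, out_path, format=format)
    by_cat: dict[str, list[float]] = {}
    for res in results:
        by_cat.setdefault(res.category, []).append(res.ghg_total_per_serving_g)
    mean_e = {cat: sum(v) / len(v) for cat, v in sorted(by_cat.items())}
    return BatchSummary(results=results, failures=failures, mean_e_by_category=mean_e)
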