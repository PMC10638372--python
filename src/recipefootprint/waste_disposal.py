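"""Food-waste mass and disposal-stage emissions.

Each dish generates waste from two sources: the inedible fraction D_i of every
ingredient (skins, bones, shells) and "food loss" — leftovers, direct waste
and excessive removal — a survey-derived fraction W_i of the *edible* portion:

    waste_i = Q_i D_i + Q_i (1 - D_i) W_i

Disposal assumes household incineration without power generation; only the
process emissions of collection, incineration, transport and landfill are
counted (0.1064 g CO2 per gram of waste by default), not the biogenic CO2 of
the burned food itself.

Because the food-loss share was produced and sold for nothing, its embodied
production emissions are also attributed:

    E_p,foodloss = sum_i Q_i (1 - D_i) W_i P_i I_i
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .data_model import EmissionFactors, IngredientRecord, LossRateTable, Recipe

__all__ = [
    "WasteBreakdown",
    "food_loss_rate",
    "disposal_mass",
    "disposal_footprint",
    "disposal_footprint_by_stage",
    "foodloss_production_footprint",
]


@dataclass(frozen=True)
class WasteBreakdown:
    """Waste mass of one dish in grams, split into the inedible share and the
    food-loss share, with per-ingredient-line contributions."""

    inedible_g: float
    foodloss_g: float
    contributions: list[dict] = field(default_factory=list)

    @property
    def total_g(self) -> float:
        return self.inedible_g + self.foodloss_g


def food_loss_rate(
    w_left: float, w_direct: float, w_excessive: float, u_food: float
) -> float:
    """Food-loss waste rate from survey components: (leftovers + direct waste
    + excessive removal) / food used, as a fraction."""
    if u_food <= 0:
        raise ValueError(f"food usage amount must be positive, got {u_food}")
    if min(w_left, w_direct, w_excessive) < 0:
        raise ValueError("loss components must be nonnegative")
    return (w_left + w_direct + w_excessive) / u_food


def disposal_mass(
    recipe: Recipe,
    ingredient_table: Mapping[str, IngredientRecord],
    loss_table: LossRateTable,
) -> WasteBreakdown:
    """Total food-waste mass of a dish: per line, inedible Q D plus food loss
    Q (1 - D) W, where W is the ingredient's category loss rate."""
    if not recipe.resolved:
        raise ValueError(f"recipe {recipe.recipe_id}: quantities not resolved")
    inedible = 0.0
    foodloss = 0.0
    contributions = []
    for line in recipe.lines:
        record = ingredient_table.get(line.ingredient_id)
        if record is None:
            raise KeyError(
                f"recipe {recipe.recipe_id}: unknown ingredient {line.ingredient_id!r}"
            )
        w_i = loss_table.rate(record.loss_category)
        q = line.resolved_grams or 0.0
        line_inedible = q * record.waste_rate
        line_foodloss = q * (1.0 - record.waste_rate) * w_i
        inedible += line_inedible
        foodloss += line_foodloss
        contributions.append(
            {
                "ingredient_id": line.ingredient_id,
                "inedible_g": line_inedible,
                "foodloss_g": line_foodloss,
            }
        )
    return WasteBreakdown(inedible_g=inedible, foodloss_g=foodloss, contributions=contributions)


def disposal_footprint(breakdown: WasteBreakdown, factors: EmissionFactors) -> float:
    """Disposal-stage CO2 in grams: total waste mass times the incineration
    process factor."""
    return breakdown.total_g * factors.disposal_g_per_g_waste


def disposal_footprint_by_stage(
    breakdown: WasteBreakdown, factors: EmissionFactors
) -> dict[str, float]:
    """Disposal CO2 split proportionally across treatment stages (collection,
    incineration, transport, landfill)."""
    stage_total = sum(factors.disposal_stage_breakdown.values())
    total = disposal_footprint(breakdown, factors)
    return {
        stage: total * share / stage_total
        for stage, share in factors.disposal_stage_breakdown.items()
    }


def foodloss_production_footprint(
    recipe: Recipe,
    ingredient_table: Mapping[str, IngredientRecord],
    loss_table: LossRateTable,
) -> float:
    """Production-and-sales CO2 (g) embodied in the food-loss share of a dish:
    sum_i Q_i (1 - D_i) W_i P_i I_i.  Subtracting this from the production
    footprint gives the emissions of the food actually eaten."""
    if not recipe.resolved:
        raise ValueError(f"recipe {recipe.recipe_id}: quantities not resolved")
    total = 0.0
    for line in recipe.lines:
        record = ingredient_table.get(line.ingredient_id)
        if record is None:
            raise KeyError(
                f"recipe {recipe.recipe_id}: unknown ingredient {line.ingredient_id!r}"
            )
        w_i = loss_table.rate(record.loss_category)
        q = line.resolved_grams or 0.0
        total += q * (1.0 - record.waste_rate) * w_i * record.unit_price * record.emission_intensity
    return total
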