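"""Per-serving nutrient content of a recipe.

Only the edible portion contributes: each line's recipe weight Q_i is reduced
by the ingredient's inedible waste rate D_i before multiplying by the nutrient
density N_ij (per gram of edible portion), then the total is divided by the
number of servings S:

    N_j = sum_i Q_i (1 - D_i) N_ij / S

Cooking losses and nutrient denaturation are deliberately not modelled, and
unmeasured or trace nutrients count as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .data_model import NUTRIENTS, IngredientRecord, Recipe

__all__ = ["NutrientVector", "edible_mass", "nutrients_per_serving"]


@dataclass(frozen=True)
class NutrientVector:
    """Amounts of the fixed 17-nutrient set, one per serving, in the units of
    ``data_model.NUTRIENTS`` (kcal, g, mg or ug per nutrient)."""

    amounts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.amounts.items():
            if name not in NUTRIENTS:
                raise ValueError(f"unknown nutrient {name!r}")
            if value < 0:
                raise ValueError(f"negative nutrient amount {name} = {value}")
        # fill unmeasured nutrients with 0 so every vector is complete
        for name in NUTRIENTS:
            self.amounts.setdefault(name, 0.0)

    def __getitem__(self, nutrient: str) -> float:
        return self.amounts[nutrient]


def edible_mass(resolved_grams: float, waste_rate: float) -> float:
    """Edible mass Q (1 - D) of a line: recipe weight less the inedible share
    (skins, bones, shells, cores)."""
    if resolved_grams < 0:
        raise ValueError(f"negative quantity {resolved_grams}")
    if not 0.0 <= waste_rate <= 1.0:
        raise ValueError(f"waste rate {waste_rate} outside [0, 1]")
    return resolved_grams * (1.0 - waste_rate)


def nutrients_per_serving(
    recipe: Recipe, ingredient_table: Mapping[str, IngredientRecord]
) -> NutrientVector:
    """Aggregate nutrient amounts per serving over all ingredient lines."""
    if not recipe.resolved:
        raise ValueError(f"recipe {recipe.recipe_id}: quantities not resolved")
    totals = {name: 0.0 for name in NUTRIENTS}
    for line in recipe.lines:
        record = ingredient_table.get(line.ingredient_id)
        if record is None:
            raise KeyError(
                f"recipe {recipe.recipe_id}: unknown ingredient {line.ingredient_id!r}"
            )
        edible = edible_mass(line.resolved_grams, record.waste_rate)  # type: ignore[arg-type]
        for name in NUTRIENTS:
            totals[name] += edible * record.density(name)
    return NutrientVector({name: totals[name] / recipe.servings for name in NUTRIENTS})
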