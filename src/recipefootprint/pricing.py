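"""Ingredient unit-price derivation and per-serving recipe cost.

Unit prices come from a household expenditure survey where available; items
covered only by a retail price-statistics survey are corrected by the mean
survey/retail price ratio over items present in both; items in neither survey
fall back to the mean resolved price of their category, and finally to a named
substitute item.  Prices are JPY per 100 g at the file interface (the survey
convention) and JPY per gram internally.

The per-serving cost of a dish is

    P = sum_i Q_i P_i / S

over the *full* recipe weight Q_i, inedible parts included — the shopper buys
the whole carrot.  Storage, cooking and disposal costs are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .data_model import IngredientRecord, Recipe

__all__ = [
    "PriceSource",
    "load_price_sources",
    "correction_coefficient",
    "derive_unit_price",
    "resolve_all_prices",
    "price_per_serving",
]


@dataclass(frozen=True)
class PriceSource:
    """Price evidence for one survey food item (prices in JPY per 100 g)."""

    item: str
    survey_price: Optional[float] = None
    retail_price: Optional[float] = None
    category: str = ""
    substitution_target: Optional[str] = None


def load_price_sources(path: str | Path) -> dict[str, PriceSource]:
    """Read the price-sources CSV (item, survey_price_jpy_per_100g,
    retail_price_jpy_per_100g, category, substitution_target)."""
    df = pd.read_csv(path)

    def opt(v) -> Optional[float]:
        return None if pd.isna(v) else float(v)

    sources = {}
    for _, row in df.iterrows():
        item = str(row["item"])
        target = row.get("substitution_target")
        sources[item] = PriceSource(
            item=item,
            survey_price=opt(row.get("survey_price_jpy_per_100g")),
            retail_price=opt(row.get("retail_price_jpy_per_100g")),
            category=str(row.get("category", "")),
            substitution_target=None if pd.isna(target) else str(target),
        )
    return sources


def correction_coefficient(sources: Mapping[str, PriceSource]) -> float:
    """Mean survey/retail price ratio over items priced in both surveys.

    Applied to retail-only items to adjust statistical retail prices toward
    actual household purchase prices.
    """
    ratios = [
        s.survey_price / s.retail_price
        for s in sources.values()
        if s.survey_price is not None and s.retail_price is not None and s.retail_price > 0
    ]
    if not ratios:
        raise ValueError("correction coefficient undefined: no item has both prices")
    return sum(ratios) / len(ratios)


def _direct_price(source: PriceSource, coefficient: float) -> Optional[float]:
    # paths 1-2 only; category averaging and substitution never recurse through
    # other indirect items, avoiding circular definitions
    if source.survey_price is not None:
        return source.survey_price
    if source.retail_price is not None:
        return source.retail_price * coefficient
    return None


def derive_unit_price(
    item: str, sources: Mapping[str, PriceSource], coefficient: float
) -> float:
    """Resolve one item's unit price (JPY per 100 g) through the four-path
    cascade: survey price, corrected retail price, category mean, substitute.
    """
    source = sources.get(item)
    if source is None:
        raise KeyError(f"unknown price item {item!r}")
    attempted = []
    direct = _direct_price(source, coefficient)
    if direct is not None:
        return direct
    attempted += ["household survey price", "corrected retail price"]
    if source.category:
        peers = [
            _direct_price(peer, coefficient)
            for peer in sources.values()
            if peer.item != item and peer.category == source.category
        ]
        peers = [p for p in peers if p is not None]
        if peers:
            return sum(peers) / len(peers)
    attempted.append(f"category mean ({source.category!r})")
    if source.substitution_target is not None:
        target = sources.get(source.substitution_target)
        if target is not None:
            sub = _direct_price(target, coefficient)
            if sub is not None:
                return sub
    attempted.append(f"substitution ({source.substitution_target!r})")
    raise ValueError(f"cannot price item {item!r}; attempted: {', '.join(attempted)}")


def resolve_all_prices(sources: Mapping[str, PriceSource]) -> dict[str, float]:
    """Resolve every item, returning JPY per 100 g; the correction coefficient
    is computed once globally from the dually-priced items."""
    coefficient = correction_coefficient(sources)
    return {item: derive_unit_price(item, sources, coefficient) for item in sources}


def price_per_serving(
    recipe: Recipe, ingredient_table: Mapping[str, IngredientRecord]
) -> float:
    """Ingredient cost of one serving: sum of full line weights times per-gram
    unit prices, divided by servings."""
    if not recipe.resolved:
        raise ValueError(f"recipe {recipe.recipe_id}: quantities not resolved")
    total = 0.0
    for line in recipe.lines:
        record = ingredient_table.get(line.ingredient_id)
        if record is None:
            raise KeyError(
                f"recipe {recipe.recipe_id}: no price for ingredient {line.ingredient_id!r}"
            )
        total += line.resolved_grams * record.unit_price  # type: ignore[operator]
    return total / recipe.servings
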