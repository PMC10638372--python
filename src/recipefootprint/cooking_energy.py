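"""Cooking-stage energy demand and CO2 footprint.

Electric appliances (microwave, oven, rice cooker) are metered directly:
microwave output power times time divided by a conversion efficiency, oven
power times time, and a fixed rice-cooker cycle (cook + keep-warm) independent
of the rice amount.

Gas-stove methods are modelled thermodynamically from the ingredients instead
of from burner settings, since recipes rarely state flame level or exact
times.  The building blocks are:

* bringing water (or oil) from room temperature to target:  m c dK / eta_h
* holding a boil, balancing evaporation:  v S_p H_w dT / eta_b
* heating the food itself:  sum_i Q_i c_i dK / eta

with ingredient specific heats c_i estimated from proximate composition
(moisture / solids / fat / ash mass fractions) when no handbook value is
available.  Per method:

* simmer — boil the stated water, hold for 2/3 of the cook time, heat food;
* boil — water is 5x the ingredient mass, hold fixed at 10 min, heat food;
* steam — water fills 60% of a 15 cm-deep standard pot, hold 2/3 cook time;
* stir-fry — heat food through a pan only partly covered by food (correction
  factor alpha inflates the demand), temperature rise 100 K;
* fry — heat oil from room to frying temperature (160 K rise) plus heat food
  (130 K rise); evaporation from the food is deliberately not modelled, so
  frying energy is a mild underestimate.

A dish cooked by several gas methods takes the *average* of the per-method
footprints (the heat absorbed by the food is roughly the same whichever
method finished it); electric-appliance energy is added on top:

    E_c = W_e [kWh] x electricity factor + mean_i(W_g,i [MJ]) x city-gas factor
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .data_model import (
    Appliance,
    CookingStep,
    EmissionFactors,
    EnergyConstants,
    GasMethod,
    IngredientRecord,
    MassFractions,
    Recipe,
)

__all__ = [
    "MethodEnergy",
    "CookingFootprint",
    "specific_heat",
    "microwave_energy",
    "oven_energy",
    "rice_cooker_energy",
    "water_boil_energy",
    "post_boil_holding_energy",
    "ingredient_heating_energy",
    "gas_method_energy",
    "cooking_footprint",
    "recipe_uses_rice",
    "J_PER_WH",
    "RICE_CATEGORY_TAG",
]

J_PER_WH = 3600.0
RICE_CATEGORY_TAG = "grains:rice"

HIGH_ASH_THRESHOLD = 0.1
LOW_FAT_THRESHOLD = 0.01
_HEAT_SCALE = 4187.0  # J/(kg K), specific heat of water in the composition formulas


@dataclass(frozen=True)
class MethodEnergy:
    """Energy demand of one cooking method: joules for gas methods, watt-hours
    for electric appliances, with an additive component breakdown in the same
    unit (boil_water / hold / heat_food / heat_oil / appliance)."""

    label: str
    energy: float
    energy_class: str  # "gas" | "electric"
    components: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.energy < 0:
            raise ValueError(f"negative energy {self.energy}")
        if self.components:
            total = sum(self.components.values())
            if abs(total - self.energy) > 1e-6 * max(1.0, abs(self.energy)):
                raise ValueError(
                    f"{self.label}: components sum {total} != total {self.energy}"
                )


def specific_heat(fractions: MassFractions, override: Optional[float] = None) -> float:
    """Specific heat of an ingredient in J/(g K).

    A handbook override wins outright.  Otherwise dispatch on composition:
    ash-rich foods (ash fraction >= 0.1, e.g. seasonings) use the five-term
    Heldman–Singh formula; low-fat foods (fat <= 1%) use the two-term
    water/solids formula; everything else uses the three-term water/fat/solids
    formula.  Formula outputs are J/(kg K) and are divided by 1000.
    """
    if override is not None:
        if override <= 0:
            raise ValueError(f"non-positive specific-heat override {override}")
        return override
    m = fractions
    total = m.moisture + m.protein + m.carbohydrate + m.fat + m.ash
    if total == 0.0:
        raise ValueError("composition unknown: all mass fractions zero and no override")
    if m.ash >= HIGH_ASH_THRESHOLD:
        c = (
            4187.0 * m.moisture
            + 1424.0 * m.carbohydrate
            + 1549.0 * m.protein
            + 1675.0 * m.fat
            + 837.0 * m.ash
        )
    elif m.fat <= LOW_FAT_THRESHOLD:
        c = (1.0 * m.moisture + 0.2 * m.solids) * _HEAT_SCALE
    else:
        c = (1.0 * m.moisture + 0.5 * m.fat + 0.33 * m.solids) * _HEAT_SCALE
    return c / 1000.0


def microwave_energy(
    power_watts: float, duration_seconds: float, constants: EnergyConstants
) -> float:
    """Microwave electricity demand in J: output power x time over the
    electricity-to-heat conversion efficiency."""
    if power_watts < 0 or duration_seconds < 0:
        raise ValueError("negative power or duration")
    return power_watts * duration_seconds / constants.eta_microwave


def oven_energy(power_watts: float, duration_seconds: float) -> float:
    """Oven electricity demand in J: rated power x time, no efficiency divisor
    (rated consumption is already electrical input)."""
    if power_watts < 0 or duration_seconds < 0:
        raise ValueError("negative power or duration")
    return power_watts * duration_seconds


def rice_cooker_energy(constants: EnergyConstants) -> float:
    """Rice-cooker electricity demand in Wh: one cook cycle plus keep-warm
    time, independent of the amount of rice."""
    return constants.rice_cook_wh + constants.rice_warm_hours * constants.rice_warm_wh_per_hour


def water_boil_energy(m_w: float, constants: EnergyConstants) -> float:
    """Gas energy (J) to bring ``m_w`` grams of water from room temperature to
    the boil, at the during-heating efficiency."""
    if m_w < 0:
        raise ValueError(f"negative water mass {m_w}")
    return m_w * constants.c_water * constants.dk_boil / constants.eta_heating


def post_boil_holding_energy(hold_minutes: float, constants: EnergyConstants) -> float:
    """Gas energy (J) to hold a rolling boil for ``hold_minutes``, balancing
    evaporation from the pot surface, at the after-boil efficiency."""
    if hold_minutes < 0:
        raise ValueError(f"negative holding time {hold_minutes}")
    return (
        constants.evaporation_rate
        * constants.pot_bottom_area_cm2
        * constants.latent_heat_water
        * hold_minutes
        / constants.eta_after_boil
    )


def ingredient_heating_energy(
    recipe: Recipe,
    ingredient_table: Mapping[str, IngredientRecord],
    delta_k: float,
    efficiency: float,
    alpha: float = 1.0,
) -> float:
    """Gas energy (J) to raise every ingredient line by ``delta_k`` kelvin:
    sum Q_i c_i dK / (efficiency x alpha), with c_i from ``specific_heat``."""
    if delta_k <= 0:
        raise ValueError(f"non-positive temperature rise {delta_k}")
    if not 0 < efficiency <= 1 or not 0 < alpha <= 1:
        raise ValueError("efficiency and alpha must lie in (0, 1]")
    if not recipe.resolved:
        raise ValueError(f"recipe {recipe.recipe_id}: quantities not resolved")
    total = 0.0
    for line in recipe.lines:
        record = ingredient_table.get(line.ingredient_id)
        if record is None:
            raise KeyError(
                f"recipe {recipe.recipe_id}: unknown ingredient {line.ingredient_id!r}"
            )
        c_i = specific_heat(record.mass_fractions, record.specific_heat_override)
        total += line.resolved_grams * c_i * delta_k  # type: ignore[operator]
    return total / (efficiency * alpha)


def _hold_minutes(
    step: Optional[CookingStep], recipe: Recipe, constants: EnergyConstants, default: Optional[float]
) -> float:
    if step is not None and step.post_boil_minutes is not None:
        return step.post_boil_minutes
    if default is not None:
        return default
    return constants.simmer_hold_time_fraction * recipe.cook_time_minutes


def gas_method_energy(
    method: GasMethod,
    recipe: Recipe,
    ingredient_table: Mapping[str, IngredientRecord],
    constants: EnergyConstants,
    step: Optional[CookingStep] = None,
) -> MethodEnergy:
    """Energy demand (J) of one gas method applied to the whole dish.

    All ingredient lines participate in food heating for every method (the
    per-method footprints are later averaged over the dish, not split by
    step).  Simmer requires the step's water mass; fry requires its oil mass.
    """
    c = constants
    components: dict[str, float] = {}
    if method in (GasMethod.SIMMER, GasMethod.BOIL, GasMethod.STEAM):
        if method is GasMethod.SIMMER:
            if step is None or step.water_grams is None:
                raise ValueError(f"recipe {recipe.recipe_id}: simmer step requires water_grams")
            m_w = step.water_grams
            hold = _hold_minutes(step, recipe, c, default=None)
        elif method is GasMethod.BOIL:
            m_w = c.boil_water_multiple * recipe.total_grams()
            hold = _hold_minutes(step, recipe, c, default=c.boil_hold_minutes)
        else:  # steam
            m_w = c.steam_fill_fraction * c.pot_bottom_area_cm2 * c.pot_depth_cm
            hold = _hold_minutes(step, recipe, c, default=None)
        components["boil_water"] = water_boil_energy(m_w, c)
        components["hold"] = post_boil_holding_energy(hold, c)
        components["heat_food"] = ingredient_heating_energy(
            recipe, ingredient_table, c.dk_boil, c.eta_food_boil_methods()
        )
    elif method is GasMethod.STIR_FRY:
        components["heat_food"] = ingredient_heating_energy(
            recipe, ingredient_table, c.dk_stir_fry, c.eta_heating, c.pan_coverage
        )
    elif method is GasMethod.FRY:
        if step is None or step.oil_grams is None:
            raise ValueError(f"recipe {recipe.recipe_id}: fry step requires oil_grams")
        components["heat_oil"] = step.oil_grams * c.c_oil * c.dk_oil / c.eta_heating
        components["heat_food"] = ingredient_heating_energy(
            recipe, ingredient_table, c.dk_deep_fry, c.eta_heating
        )
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown gas method {method!r}")
    return MethodEnergy(
        label=method.value,
        energy=sum(components.values()),
        energy_class="gas",
        components=components,
    )


def recipe_uses_rice(
    recipe: Recipe, ingredient_table: Mapping[str, IngredientRecord]
) -> bool:
    """True when any line's ingredient carries the rice category tag."""
    for line in recipe.lines:
        record = ingredient_table.get(line.ingredient_id)
        if record is not None and record.loss_category == RICE_CATEGORY_TAG:
            return True
    return False


@dataclass(frozen=True)
class CookingFootprint:
    """Cooking-stage CO2 result: total grams, the electric demand in kWh, the
    per-method gas energies, and whether a rice-cooker cycle was auto-added."""

    total_g: float
    electric_kwh: float
    gas_method_energies: dict[str, MethodEnergy]
    gas_mean_mj: float
    electric_energies: list[MethodEnergy] = field(default_factory=list)
    rice_cooker_added: bool = False
    warning: Optional[str] = None


def cooking_footprint(
    recipe: Recipe,
    ingredient_table: Mapping[str, IngredientRecord],
    constants: EnergyConstants,
    factors: EmissionFactors,
) -> CookingFootprint:
    """Cooking-stage CO2 footprint of a dish in grams.

    Gas methods are deduplicated by label (each method evaluated once over the
    whole dish, from the first step carrying it) and averaged in MJ; electric
    appliance energies are summed in kWh and added.  A dish listing rice as an
    ingredient gets a rice-cooker cycle even without an explicit step.  A dish
    with no steps and no rice has zero cooking footprint (a warning is
    recorded and emitted).
    """
    electric: list[MethodEnergy] = []
    gas: dict[str, MethodEnergy] = {}
    has_rice_step = False
    for step in recipe.steps:
        if step.appliance is Appliance.MICROWAVE:
            joules = microwave_energy(step.power_watts, step.duration_seconds, constants)
            electric.append(
                MethodEnergy("microwave", joules / J_PER_WH, "electric",
                             {"appliance": joules / J_PER_WH})
            )
        elif step.appliance is Appliance.OVEN:
            power = step.power_watts if step.power_watts is not None else constants.oven_power_watts
            joules = oven_energy(power, step.duration_seconds)
            electric.append(
                MethodEnergy("oven", joules / J_PER_WH, "electric",
                             {"appliance": joules / J_PER_WH})
            )
        elif step.appliance is Appliance.RICE_COOKER:
            has_rice_step = True
        else:  # gas stove
            if step.method.value not in gas:
                gas[step.method.value] = gas_method_energy(
                    step.method, recipe, ingredient_table, constants, step
                )

    rice_added = False
    if has_rice_step or recipe_uses_rice(recipe, ingredient_table):
        wh = rice_cooker_energy(constants)
        electric.append(MethodEnergy("rice_cooker", wh, "electric", {"appliance": wh}))
        rice_added = not has_rice_step and bool(wh)

    warning = None
    if not electric and not gas:
        warning = f"recipe {recipe.recipe_id}: no cooking steps and no rice; E_c = 0"
        warnings.warn(warning, stacklevel=2)

    electric_kwh = sum(e.energy for e in electric) / 1000.0
    gas_mean_mj = (
        sum(m.energy for m in gas.values()) / len(gas) / 1e6 if gas else 0.0
    )
    total = (
        electric_kwh * factors.electricity_g_per_kwh
        + gas_mean_mj * factors.city_gas_g_per_mj
    )
    return CookingFootprint(
        total_g=total,
        electric_kwh=electric_kwh,
        gas_method_energies=gas,
        gas_mean_mj=gas_mean_mj,
        electric_energies=electric,
        rice_cooker_added=rice_added,
        warning=warning,
    )
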