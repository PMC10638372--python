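# Methods

This note documents the models implemented in `recipefootprint`, the
constants they use, the choices made where the design was genuinely open, and
what the synthetic fixtures do and do not establish.

## Scope and data flow

A recipe is a structured object: ingredient lines (value + unit), servings,
total cook time, and structured cooking steps (appliance, gas method,
power/duration/water/oil parameters). The engine deliberately does not parse
free-text directions; a small keyword→method mapper
(`data_model.method_from_keyword`) is provided as convenience plumbing only.
All reference data arrive as plain files: an ingredient CSV (nutrient
densities per 100 g, waste rate, proximate composition, unit price per
100 g, emission intensity, loss-category tag), a loss-rate CSV, a price-source
CSV and a piece-mass CSV. Densities and prices are converted to per-gram on
ingest; results are written at full float precision so a write/read round
trip is lossless (presentation rounding to one decimal happens only in the
CLI summary).

## Quantity resolution

Milliliters convert 1:1 to grams (condiments and liquids are treated as
water-dense); vague amounts ("a pinch", "appropriate amount") are exactly
0 g; count units ("2 eggs") multiply by a piece-mass table that ships as
editable data, not code. After resolution every line has a gram value;
nothing downstream accepts unresolved recipes.

## Nutrients

Per-serving nutrient *j* is Σᵢ Qᵢ(1−Dᵢ)Nᵢⱼ/S over the fixed 17-nutrient set
(energy, macronutrients, fiber, saturated fat, salt equivalent, cholesterol,
7 minerals/vitamins in mg, vitamin A and folic acid in µg). Only the edible
portion counts; nutrient retention through cooking is *not* modelled, and
unmeasured nutrients contribute zero. Energy is taken from the table's own
energy density rather than recomputed from macronutrients, matching
food-composition-table practice.

## Prices

The unit-price cascade mirrors how household survey data get patched with
retail statistics: (1) household-survey purchase price when present;
(2) retail-statistics price times a correction coefficient — the mean
survey/retail ratio over items priced in both sources, computed once
globally (a per-category coefficient is possible via the API but is not the
default); (3) the mean of the *directly resolved* (paths 1–2) prices of
same-category items — restricting to direct resolutions avoids circular
definitions, on which the source procedure is silent; (4) a named substitute
item's direct price. Recipe cost uses the full purchased weight including
inedible parts.

## Production-stage footprint

EEIO accounting: spend per ingredient (Qᵢ Pᵢ, JPY) times a sector emission
intensity Iᵢ (g-CO₂e/JPY) at consumer prices. This covers the supply chain
from production through retail. The food-loss-attributed share Eₚ,foodloss is
reported alongside Eₚ (Eₚ always includes it; consumed-food emissions are
Eₚ − Eₚ,foodloss).

## Cooking-stage energy

Constants (all config-overridable through a YAML file):

| symbol | meaning | default |
|---|---|---|
| η_m | microwave conversion efficiency | 0.71 |
| η_h | gas heat efficiency during heating | 0.37 |
| η_b | gas heat efficiency after boiling | 0.42 |
| c_w | specific heat of water | 4.20 J/(g·K) |
| H_w | latent heat of vaporization | 2250 J/g |
| c_o | specific heat of oil | 1.96 J/(g·K) |
| ΔK_b | room → boiling rise | 80 K |
| ΔK_f | food rise in stir-fry | 100 K |
| ΔK_o | room → frying-oil rise | 160 K |
| ΔK_d | food rise in deep-frying | 130 K |
| v | pot evaporation rate | 0.06 g/(min·cm²) |
| S_p | pot bottom area | 314 cm² |
| α | pan coverage correction | 0.75 |

plus pot depth 15 cm, steam fill fraction 0.6, boil-water multiple 5,
boil holding time 10 min, simmer/steam holding fraction 2/3 of cook time,
rice-cooker 156 Wh + 13.9 Wh/h × 2 h keep-warm = 183.8 Wh. The oven power
default (1000 W) is a typical oven-range element, used only when a step does
not state its own power; unlike the other constants it is not a published
measurement.

Method models: simmer uses the step's stated water; boil estimates water as
5× the ingredient mass; steam uses the fixed pot geometry (0.6·314·15 =
2826 g). Stir-fry heats food at η_h·α (the uncovered pan area loses heat to
the air); frying heats oil and food at η_h and deliberately omits water
evaporation from the food (hard to estimate; the result is a mild
underestimate). Ingredient heating in the water-based methods uses the
after-boil efficiency η_b as printed in the source material for that model;
whether η_h would be more physical for food heated from room temperature is
ambiguous, so the choice is exposed as
`EnergyConstants.food_heating_eta_boil_methods`.

Specific heats dispatch on composition: a handbook override wins; ash ≥ 0.1
(seasonings) takes the five-term Heldman–Singh formula; fat ≤ 1% takes the
two-term water/solids formula (protein and carbohydrate differ little in
specific heat and are pooled as "solids"); otherwise the three-term
water/fat/solids formula. Formula outputs in J/(kg·K) are divided by 1000.

Footprint composition: gas methods are deduplicated by label and each is
computed once *over the whole dish* (the heat absorbed by the food is
roughly independent of which method finished it, so per-method footprints
are averaged, not summed; splitting ingredients per step is a config
extension that is off by default). When two steps share a label the first
step's parameters are used. Electric energies are summed — including the
rice-cooker cycle, which is added automatically whenever a rice-class
ingredient (`grains:rice` tag) appears, even without an explicit step — and
converted at 3600 J/Wh. Emission factors: 441 g-CO₂/kWh electricity,
49.9 g-CO₂/MJ city gas. A recipe with no steps and no rice has E_c = 0 and
emits a warning rather than failing. "Grilling" keywords map to the stir-fry
model; no separate grilling model is invented.

## Disposal stage

Waste per line is inedible mass Qᵢ Dᵢ plus food loss Qᵢ(1−Dᵢ)Wᵢ — the loss
rate applies to the edible portion only, since leftovers, direct waste and
excessive removal are all defined on it. Loss rates come per category from
survey components ((left + direct + excessive)/used); lookup falls back from
`class:subclass` to `class`. Disposal assumes household incineration without
power generation; the factor 0.1064 g-CO₂/g is exactly the stage breakdown
(collection 24, incineration 73, transport 3.7, landfill 5.7 kg per 1000 kg)
divided by 1000, and the model counts only these process emissions, not the
biogenic CO₂ of the burned food. Leftovers' cooking energy stays attributed
to E_c, not E_d.

## Dish categorization

Ingredients carry a hierarchical `loss_category` tag (`meat:pork`,
`grains:rice`, `vegetables`, …). A meat/seafood ingredient classifies the
dish outright; two distinct meat/seafood classes in one recipe is an error
(the engine refuses rather than guesses — the scheme assumes they do not
co-occur). Otherwise the plant class (grains, eggs, vegetables, mushrooms,
beans) with the largest total mass wins; exact ties break by that fixed
class order, a documented convention since no tie rule exists in the source
procedure. Oils, seasonings and dairy never drive categorization.

## Price-bounds uncertainty

Each ingredient may carry (min, max) unit prices (e.g. across income
groups). The production footprint is linear in prices, so the analysis
simply re-evaluates Eₚ (and the per-serving total; E_c and E_d are
price-independent) at all-min and all-max prices and reports absolute ranges
and relative half-ranges against the point estimate.

## Synthetic fixtures

`synthetic_fixtures` generates, from one seeded NumPy generator, an
ingredient table (guaranteeing every specific-heat branch and dish class is
reachable), loss-rate/price-source/piece-mass tables, and a recipe set
covering every appliance and gas method plus vague/count quantities and a
rice-implied recipe. Fixtures are emitted through the standard CSV/JSON
interfaces so the readers and CLI are exercised end to end, and identical
seeds yield byte-identical files. The generator targets *structural*
realism — magnitudes of Japanese retail prices, EEIO intensities and
proximate compositions — not statistical realism of any national diet:
passing tests demonstrate correctness of the accounting and energy models on
valid inputs, not calibration against real consumption data.

## Problem sizes and numerical choices

The property suites evaluate ~1000 generated recipes (72 seeds × 14
recipes), comfortably exercising every code path; all comparisons use
absolute/relative tolerances of 1e-9 for accounting identities and 1e-6 for
energy-component sums. Degenerate inputs are defined, not special-cased:
zero quantities give zero everywhere, fully inedible ingredients give a zero
nutrient vector, an empty result list writes a header-only file.

## Known limitations

- Cooking energy ignores lid use, flame level (medium heat without a lid is
  the only calibration), standby power, and evaporation during frying.
- Nutrients ignore cooking losses and bioavailability.
- Unit prices do not distinguish domestic/imported goods or regional
  variation beyond the optional min/max bounds.
- The disposal model covers only incineration; composting/methanation routes
  are out of scope.
- Ingredient-name normalization from free text is out of scope; inputs are
  already structured and mapped to the reference table.
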