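# recipefootprint

Per-serving **nutrients**, **ingredient cost**, and a **three-stage carbon
footprint** (production/sales, cooking, disposal) for structured recipes.

The package is aimed at researchers and recipe platforms who want dish-level
sustainability information: consumers eat dishes, not raw ingredients, so
nutritional and environmental accounting has to happen at the recipe level,
combining ingredient quantities with the way the dish is cooked and the waste
it generates.

## The model

For a recipe with ingredient weights *Qᵢ* (g), inedible waste rates *Dᵢ*,
nutrient densities *Nᵢⱼ* (per g edible portion), unit prices *Pᵢ* (JPY/g),
EEIO emission intensities *Iᵢ* (g-CO₂e/JPY), food-loss rates *Wᵢ*, and *S*
servings:

- **Nutrients** (edible portion only, cooking losses ignored):
  *Nⱼ = Σᵢ Qᵢ (1 − Dᵢ) Nᵢⱼ / S*
- **Price** (whole purchased weight, inedible parts included):
  *P = Σᵢ Qᵢ Pᵢ / S*
- **Production and sales** (EEIO: emissions embodied per yen spent):
  *Eₚ = Σᵢ Qᵢ Pᵢ Iᵢ*
- **Cooking**: electric appliances are metered directly (microwave
  power×time/η with η = 0.71, oven power×time, rice cooker fixed at 183.8 Wh
  per cycle incl. 2 h keep-warm); gas-stove methods are modelled
  thermodynamically — boil water (*m_w c_w ΔK/η_h*), hold the boil
  (*v S_p H_w ΔT/η_b*), heat the food (*Σ Qᵢ cᵢ ΔK/η*) — with ingredient
  specific heats *cᵢ* estimated from proximate composition. A dish cooked by
  several gas methods takes the **mean** of the per-method footprints;
  electricity is added on top:
  *E_c = W_e·441 g/kWh + mean(W_g)·49.9 g/MJ*
- **Disposal** (incineration without power generation):
  *E_d = Σᵢ (Qᵢ Dᵢ + Qᵢ (1 − Dᵢ) Wᵢ) × 0.1064 g-CO₂/g*, and the production
  emissions embodied in the food-loss share,
  *Eₚ,foodloss = Σᵢ Qᵢ (1 − Dᵢ) Wᵢ Pᵢ Iᵢ*.
- **Total per serving**: *E = (Eₚ + E_c + E_d)/S*.

See `docs/methods.md` for assumptions, constants and limitations.

## Worked example

Two dishes evaluated against the small reference tables in `examples/`:

```sh
recipefootprint evaluate \
  --recipes examples/recipes.json \
  --ingredients examples/ingredients.csv \
  --loss-rates examples/loss_rates.csv \
  --piece-mass examples/piece_mass.csv \
  --uncertainty --out results.csv
```

prints

```
evaluated 2 recipes, 0 failures
  mean E per serving [grains]: 244.1 g CO2e
  mean E per serving [pork]: 924.2 g CO2e
```

and `results.csv` contains (rounded here for display):

```
              recipe_id category  ghg_production_g  ghg_cooking_g  ghg_disposal_g  ghg_total_per_serving_g  price_per_serving_jpy  disposal_amount_g
stir_fried_pork_cabbage     pork            1820.7           23.7             4.1                    924.2                  180.1               38.4
         egg_fried_rice   grains             390.8           94.8             2.6                    244.1                   74.2               24.8
```

Reading the first row: producing and retailing the pork dish's ingredients
embodies 1.82 kg CO₂e; stir-frying it on a gas stove adds 24 g; incinerating
its 38 g of waste (cabbage cores plus expected food loss) adds 4 g; divided
by two servings the dish costs 180 JPY and 924 g CO₂e per serving. The fried
rice is cheaper and lighter, but note its cooking share is larger — the rice
cooker cycle (181 Wh × 441 g/kWh) is added automatically because rice appears
as an ingredient even though no rice-cooker step is written.

The `fixtures` subcommand (`recipefootprint fixtures --seed 1 --out DIR`)
generates a complete synthetic world (ingredient table, loss rates, price
sources, recipes) for testing without any external data.

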