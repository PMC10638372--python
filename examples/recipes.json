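{
 "recipes": [
  {
   "recipe_id": "stir_fried_pork_cabbage",
   "name": "Stir-fried pork and cabbage",
   "servings": 2,
   "cook_time_minutes": 15,
   "ingredients": [
    {"ingredient_id": "pork_loin", "quantity": {"value": 200, "unit": "g"}},
    {"ingredient_id": "cabbage", "quantity": {"value": 150, "unit": "g"}},
    {"ingredient_id": "canola_oil", "quantity": {"value": 15, "unit": "ml"}},
    {"ingredient_id": "soy_sauce", "quantity": {"value": 18, "unit": "ml"}}
   ],
   "steps": [
    {"appliance": "gas_stove", "method": "stir_fry"}
   ]
  },
  {
   "recipe_id": "egg_fried_rice",
   "name": "Egg fried rice",
   "servings": 2,
   "cook_time_minutes": 20,
   "ingredients": [
    {"ingredient_id": "rice", "quantity": {"value": 300, "unit": "g"}},
    {"ingredient_id": "egg", "quantity": {"value": 2, "unit": "count"}},
    {"ingredient_id": "canola_oil", "quantity": {"value": 10, "unit": "ml"}},
    {"ingredient_id": "soy_sauce", "quantity": {"value": 0, "unit": "vague"}}
   ],
   "steps": [
    {"appliance": "gas_stove", "method": "stir_fry"}
   ]
  }
 ]
}
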