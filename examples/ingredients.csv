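ingredient_id,canonical_name,energy_kcal_per_100g,protein_g_per_100g,fat_g_per_100g,carbohydrate_g_per_100g,iron_mg_per_100g,vitamin_c_mg_per_100g,salt_equivalent_g_per_100g,waste_rate,m_moisture,m_protein,m_carbohydrate,m_fat,m_ash,specific_heat_override,unit_price_jpy_per_100g,price_min,price_max,emission_intensity_g_per_jpy,loss_category,price_item
cabbage,cabbage,23,1.3,0.2,5.2,0.3,41,0,0.15,0.928,0.013,0.052,0.002,0.005,,30,24,39,3.1,vegetables,fresh_vegetables
pork_loin,pork loin,263,19.3,19.2,0.2,0.3,1,0.1,0.0,0.601,0.193,0.002,0.192,0.01,,150,120,185,5.5,meat:pork,pork
rice,polished rice,342,6.1,0.9,77.6,0.8,0,0,0.0,0.145,0.061,0.776,0.009,0.004,,40,33,51,2.6,grains:rice,rice
egg,hen egg whole,142,12.2,10.2,0.4,1.5,0,0.4,0.14,0.751,0.122,0.004,0.102,0.01,,25,21,31,2.9,eggs,eggs
soy_sauce,dark soy sauce,77,7.7,0,7.9,1.7,0,14.5,0.0,0.675,0.077,0.079,0.0,0.151,,55,46,68,2.2,seasonings,seasonings
canola_oil,canola oil,921,0,100,0,0,0,0,0.0,0.0,0.0,0.0,0.999,0.0,,35,28,44,1.8,oils,cooking_oil
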