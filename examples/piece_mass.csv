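ingredient_id,grams_per_piece
egg,50
cabbage,1200
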