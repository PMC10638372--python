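loss_category,rate,w_left,w_direct,w_excessive,u_food
vegetables,,5.0,3.0,0.8,100.0
meat,0.022,,,,
grains,0.030,,,,
eggs,0.020,,,,
seasonings,0.010,,,,
oils,0.005,,,,
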