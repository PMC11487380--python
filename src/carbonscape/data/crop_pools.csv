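crop_type,maturity_cycle_years,CAG,CBG
Olive,50,9.13,2.60
Vineyards (wine grapes),20,5.6,4.46
Vineyards (other),30,5.62,4.48
Orchards,25,8.91,5.75
Other fruits,20,8.90,5.73
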