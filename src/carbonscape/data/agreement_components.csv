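component,LULC 2012,LULC 2018
chance,0.1250,0.1250
quantity,0.2976,0.2973
stratum,0.0000,0.0000
gridcell,0.5575,0.5669
dis_gridcell,0.0140,0.0084
dis_stratum,0.0000,0.0000
dis_quantity,0.0059,0.0023
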