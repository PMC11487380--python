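wetland_type,CAG,CBG,CSOIL,CDOM
Swamp,18.00,18.50,161.50,10.00
Lake related wetland,6.00,19.50,11.50,0
River related wetland,6.00,32.00,71.50,0
Beach related wetland,39.00,19.50,62.00,10.00
Mangrove wetland,48.50,106.00,206.00,3.00
Pond related wetland,18.00,6.50,17.00,0
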