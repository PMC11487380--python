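tree_type,BEF,WBD,CF,R,AMR
European beech,1.36,0.61,0.47,0.20,0.0177
Chestnut,1.33,0.49,0.47,0.28,0.0177
Turkey oak,1.45,0.69,0.47,0.24,0.0177
Larches,1.22,0.56,0.47,0.29,0.0177
Mean value,1.34,0.58,0.47,0.25,0.0177
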