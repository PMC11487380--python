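year,Kstd,Kno,Kloc,Klocstrata
2012,0.9656,0.9773,0.9755,0.9755
2018,0.9814,0.9877,0.9854,0.9854
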