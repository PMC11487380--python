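class,Settlement,Crop land,Forest land,Grassland,Wetland,Water body,Other land
Settlement,0.9862,0.0081,0.0019,0.0028,0.0000,0.0005,0.0004
Crop land,0.0058,0.9860,0.0019,0.0058,0.0000,0.0001,0.0003
Forest land,0.0001,0.0035,0.9872,0.0083,0.0000,0.0001,0.0007
Grassland,0.0004,0.0134,0.0253,0.8977,0.0000,0.0024,0.0607
Wetland,0.0000,0.0000,0.0000,0.1070,0.7920,0.1009,0.0000
Water body,0.0009,0.0008,0.0000,0.0000,0.0000,0.9963,0.0020
Other land,0.0007,0.0086,0.0083,0.0688,0.0000,0.0006,0.9131
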