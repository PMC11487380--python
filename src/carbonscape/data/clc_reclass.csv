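source_code,source_name,target_code,target_name
1,Continuous urban fabric,1,Settlement
2,Discontinuous urban fabric,1,Settlement
3,Industrial or commercial units,1,Settlement
4,Road and rail networks and associated land,1,Settlement
5,Port areas,1,Settlement
6,Airports,1,Settlement
7,Mineral extraction sites,1,Settlement
8,Dump sites,1,Settlement
9,Construction sites,1,Settlement
10,Green urban areas,1,Settlement
11,Sport and leisure facilities,1,Settlement
12,Non-irrigated arable land,2,Crop land
13,Permanently irrigated land,2,Crop land
14,Rice fields,2,Crop land
15,Vineyards,2,Crop land
16,Fruit trees and berry plantations,2,Crop land
17,Olive groves,2,Crop land
18,Pastures,4,Grassland
19,Annual crops associated with permanent crops,2,Crop land
20,Complex cultivation patterns,2,Crop land
21,Land principally occupied by agriculture with significant areas of natural vegetation,2,Crop land
22,Agro-forestry areas,3,Forest land
23,Broad-leaved forest,3,Forest land
24,Coniferous forest,3,Forest land
25,Mixed forest,3,Forest land
26,Natural grasslands,4,Grassland
27,Moors and heathland,4,Grassland
28,Sclerophyllous vegetation,4,Grassland
29,Transitional woodland-shrub,4,Grassland
30,Beaches dunes sands,7,Other land
31,Bare rocks,7,Other land
32,Sparsely vegetated areas,4,Grassland
33,Burnt areas,7,Other land
34,Glaciers and perpetual snow,7,Other land
35,Inland marshes,5,Wetland
36,Peat bogs,5,Wetland
37,Salt marshes,5,Wetland
38,Salines,5,Wetland
39,Intertidal flats,5,Wetland
40,Water courses,6,Water body
41,Water bodies,6,Water body
42,Coastal lagoons,6,Water body
43,Estuaries,6,Water body
44,Sea and ocean,6,Water body
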