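class_code,class_name,CAG,CBG,CSOIL,CDOM
1,Settlement,2,1,5,0
2,Crop land,8,5,46,1
3,Forest land,93,17,83,9
4,Grassland,1,5,66,0
5,Wetland,23,34,88,4
6,Water body,2,1,10,0
7,Other land,2,0,16,0
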