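year,class_code,class_name,area_km2
2000,1,Settlement,446.66
2000,2,Crop land,7319.45
2000,3,Forest land,5536.18
2000,4,Grassland,1482.16
2000,5,Wetland,1.25
2000,6,Water body,70.38
2000,7,Other land,262.77
2006,1,Settlement,547.42
2006,2,Crop land,7180.98
2006,3,Forest land,5482.54
2006,4,Grassland,1615.02
2006,5,Wetland,0.47
2006,6,Water body,73.52
2006,7,Other land,218.89
2012,1,Settlement,560.15
2012,2,Crop land,7151.97
2012,3,Forest land,5469.46
2012,4,Grassland,1353.51
2012,5,Wetland,0.47
2012,6,Water body,76.92
2012,7,Other land,506.37
2018,1,Settlement,560.05
2018,2,Crop land,7151.02
2018,3,Forest land,5488.18
2018,4,Grassland,1329.28
2018,5,Wetland,0.47
2018,6,Water body,83.84
2018,7,Other land,505.99
2024,1,Settlement,580.95
2024,2,Crop land,7121.24
2024,3,Forest land,5469.74
2024,4,Grassland,1306.74
2024,5,Wetland,0.47
2024,6,Water body,86.88
2024,7,Other land,553.56
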