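platform,seafloor_depth_m,area_shallow_m2,area_midwater_m2,area_base_m2,footprint_m2,shellmound_m2
Irene,74,3537,10706,621,2664,13484
Hidalgo,131,9402,62227,1662,4333,
Harvest,204,4455,73122,1544,5890,
Hermosa,183,6018,77766,1319,5203,642
Holly,64,6388,14043,984,1952,
B,57,7469,13335,1129,1979,
A,57,7671,13325,1116,1890,
Hillhouse,58,7501,13705,1141,2014,
Habitat,92,4150,21616,967,2242,
Gilda,64,6035,12591,862,2081,18290
Grace,97,4789,20279,777,3004,22754
Gail,225,5156,99596,1675,5390,655
Edith,49,8304,8056,846,2590,
Elly,78,3187,10663,568,2664,
Ellen,81,5930,20849,1064,2664,
Eureka,213,5615,101459,1809,5390,
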