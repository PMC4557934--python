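platform,habitat,surface_area_m2,ssb_density_kg_m2,ssb_kg,production_density_kg_m2_yr,production_kg_yr
Irene,shallow,3537,0.118,419,0.091,323
Irene,midwater,10706,0.118,1267,0.091,978
Irene,base,621,0.305,189,0.068,42
Irene,shellmound,13484,0.041,555,0.024,324
Hidalgo,shallow,9402,0.015,138,0.017,163
Hidalgo,midwater,62227,0.015,911,0.017,1080
Hidalgo,base,1662,0.221,367,0.032,54
Hidalgo,shellmound,,0.022,,0.008,
Harvest,shallow,4455,0.018,78,0.012,54
Harvest,midwater,73122,0.021,1520,0.013,962
Harvest,base,1544,0.072,112,0.010,16
Harvest,shellmound,,0.019,,0.004,
Hermosa,shallow,6018,0.033,200,0.020,118
Hermosa,midwater,77766,0.033,2584,0.020,1531
Hermosa,base,1319,0.126,166,0.013,17
Hermosa,shellmound,642,0.048,31,0.007,4
Holly,shallow,6388,0.031,197,0.008,53
Holly,midwater,14043,0.038,536,0.017,241
Holly,base,984,0.283,279,0.040,39
Holly,shellmound,,0.053,,0.009,
B,shallow,7469,0.022,162,0.002,15
B,midwater,13335,0.036,475,0.016,209
B,base,1129,0.158,178,0.028,31
A,shallow,7671,0.046,355,0.005,38
A,midwater,13325,0.047,625,0.013,172
A,base,1116,0.158,176,0.028,31
Hillhouse,shallow,7501,0.022,164,0.005,40
Hillhouse,midwater,13705,0.049,675,0.047,649
Hillhouse,base,1141,0.158,180,0.028,32
Habitat,shallow,4150,0.006,26,0.002,8
Habitat,midwater,21616,0.057,1222,0.023,495
Habitat,base,967,0.158,153,0.028,27
Gilda,shallow,6035,0.014,86,0.005,27
Gilda,midwater,12591,0.027,337,0.021,268
Gilda,base,862,0.345,297,0.162,140
Gilda,shellmound,18290,0.139,2534,0.068,1253
Grace,shallow,4789,0.132,631,0.058,276
Grace,midwater,20279,0.163,3296,0.077,1563
Grace,base,777,0.424,329,0.055,43
Grace,shellmound,22754,0.073,1655,0.010,238
Gail,shallow,5156,0.013,69,0.005,25
Gail,midwater,99596,0.004,419,0.004,414
Gail,base,1675,0.447,749,0.070,117
Gail,shellmound,655,0.031,20,0.005,3
Edith,shallow,8304,0.189,1570,0.038,315
Edith,midwater,8056,0.028,227,0.004,34
Edith,base,846,0.150,127,0.075,64
Edith,shellmound,,0.114,,0.030,
Elly,shallow,3187,0.100,318,0.015,46
Elly,midwater,10663,0.240,2563,0.066,704
Elly,base,568,0.688,391,0.108,61
Elly,shellmound,,0.176,,0.037,
Ellen,shallow,5930,0.070,414,0.019,115
Ellen,midwater,20849,0.283,5892,0.108,2243
Ellen,base,1064,0.408,434,0.057,61
Ellen,shellmound,,0.100,,0.016,
Eureka,shallow,5615,0.103,578,0.030,166
Eureka,midwater,101459,0.105,10679,0.035,3540
Eureka,base,1809,0.116,211,0.010,18
Eureka,shellmound,,0.005,,0.001,
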