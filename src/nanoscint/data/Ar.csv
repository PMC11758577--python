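# element=Ar Z=18 mass=39.948 k_edge_keV=3.2029 l_edge_keV=0.275 kalpha_keV=2.9577 omega_k=0.118
energy_keV,pe_cm2g,incoh_cm2g,coh_cm2g
0.25,134953,0.0129173,13.8968
0.265284,127178,0.0136464,13.8968
0.281501,115076,0.014413,13.8968
0.298711,97807.9,0.0152188,13.8968
0.316972,83131.1,0.0160651,13.8968
0.33635,70656.6,0.0169536,13.8968
0.356913,60054,0.0178857,13.8968
0.378732,51042.4,0.0188631,13.8968
0.401886,43383.1,0.0198872,13.8968
0.426455,36873.1,0.0209596,13.8968
0.452526,31340,0.0220817,13.8968
0.48019,26637.2,0.0232549,13.8968
0.509546,22640.1,0.0244805,13.8968
0.540697,19242.8,0.02576,13.8968
0.573752,16355.2,0.0270944,13.8968
0.608828,13901,0.0284848,13.8968
0.646048,11815.1,0.0299324,13.8968
0.685544,10042.1,0.0314379,13.8968
0.727454,8535.21,0.033002,13.8968
0.771926,7254.44,0.0346254,13.8968
0.819117,6165.85,0.0363083,13.8968
0.869194,5240.62,0.0380511,13.8968
0.922331,4454.22,0.0398536,13.8968
0.978717,3785.83,0.0417156,13.8968
1.03855,3217.74,0.0436367,12.9331
1.10204,2734.89,0.045616,11.5542
1.16941,2324.5,0.0476527,10.3223
1.2409,1975.69,0.0497453,9.22173
1.31677,1679.22,0.0518924,8.23851
1.39727,1427.24,0.054092,7.36013
1.48269,1213.07,0.056342,6.57539
1.57333,1031.04,0.0586399,5.87433
1.66951,876.325,0.060983,5.24801
1.77158,744.826,0.0633682,4.68847
1.87988,633.059,0.0657922,4.18858
1.99481,538.063,0.0682513,3.742
2.11676,457.323,0.0707417,3.34303
2.24616,388.698,0.0732591,2.9866
2.38348,330.371,0.0757994,2.66817
2.52919,280.796,0.0783578,2.38369
2.68381,238.66,0.0809296,2.12954
2.84789,202.847,0.08351,1.90249
3.02199,172.409,0.0860939,1.69965
3.2029,147.019,0.0886242,1.52189
3.2029,1396.68,0.0886242,1.52189
3.20674,1392.1,0.0886762,1.51843
3.40278,1183.21,0.0912518,1.35654
3.6108,1005.66,0.0938153,1.2119
3.83155,854.752,0.0963617,1.08269
4.06579,726.489,0.0988858,0.967254
4.31434,617.474,0.101382,0.864126
4.5781,524.817,0.103847,0.771993
4.85798,446.064,0.106274,0.689684
5.15496,379.129,0.108659,0.61615
5.47011,322.237,0.110997,0.550456
5.80452,273.883,0.113285,0.491767
6.15937,232.785,0.115517,0.439335
6.53592,197.854,0.117691,0.392493
6.93549,168.164,0.119802,0.350646
7.35949,142.93,0.121847,0.31326
7.8094,121.482,0.123823,0.27986
8.28683,103.253,0.125727,0.250022
8.79343,87.7588,0.127556,0.223364
9.33101,74.5899,0.129309,0.199549
9.90146,63.3971,0.130982,0.178274
10.5068,53.8839,0.132574,0.159266
11.1491,45.7982,0.134083,0.142285
11.8307,38.9258,0.135508,0.127115
12.5539,33.0847,0.136847,0.113562
13.3214,28.1201,0.1381,0.101454
14.1358,23.9004,0.139265,0.090637
15,20.314,0.140343,0.0809733
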