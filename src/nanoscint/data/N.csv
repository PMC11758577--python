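# element=N Z=7 mass=14.007 k_edge_keV=0.4099 l_edge_keV=0.015 kalpha_keV=0.3924 omega_k=0.0052
energy_keV,pe_cm2g,incoh_cm2g,coh_cm2g
0.25,20732.7,0.0331127,2.56188
0.265284,17331.3,0.0347829,2.56188
0.281501,14487.8,0.0365186,2.56188
0.298711,12110.9,0.0383208,2.56188
0.316972,10124,0.0401897,2.56188
0.33635,8463.01,0.0421258,2.56188
0.356913,7074.54,0.0441291,2.56188
0.378732,5913.88,0.0461995,2.56188
0.401886,4943.63,0.0483365,2.56188
0.4099,4657.45,0.0490623,2.56188
0.4099,51231.9,0.0490623,2.56188
0.426455,45458.2,0.0505394,2.56188
0.452526,38000.2,0.0528073,2.56188
0.48019,31765.8,0.0551388,2.56188
0.509546,26554.2,0.0575325,2.56188
0.540697,22197.6,0.0599863,2.56188
0.573752,18555.8,0.062498,2.56188
0.608828,15511.5,0.0650651,2.56188
0.646048,12966.7,0.0676848,2.56188
0.685544,10839.3,0.0703538,2.56188
0.727454,9060.98,0.0730686,2.56188
0.771926,7574.41,0.0758254,2.56188
0.819117,6331.73,0.0786202,2.56188
0.869194,5292.93,0.0814487,2.56188
0.922331,4424.56,0.0843061,2.56188
0.978717,3698.65,0.0871877,2.56188
1.03855,3091.84,0.0900886,2.38422
1.10204,2584.59,0.0930035,2.13002
1.16941,2160.55,0.0959273,1.90292
1.2409,1806.09,0.0988544,1.70003
1.31677,1509.77,0.10178,1.51877
1.39727,1262.08,0.104697,1.35684
1.48269,1055.02,0.107602,1.21218
1.57333,881.928,0.110489,1.08293
1.66951,737.236,0.113352,0.967472
1.77158,616.283,0.116186,0.864321
1.87988,515.174,0.118986,0.772167
1.99481,430.653,0.121748,0.689839
2.11676,359.999,0.124467,0.616289
2.24616,300.937,0.127138,0.55058
2.38348,251.564,0.129757,0.491877
2.52919,210.292,0.13232,0.439434
2.68381,175.791,0.134824,0.392581
2.84789,146.95,0.137266,0.350725
3.02199,122.841,0.139642,0.31333
3.20674,102.687,0.141949,0.279923
3.40278,85.8402,0.144186,0.250078
3.6108,71.757,0.146349,0.223415
3.83155,59.9844,0.148438,0.199594
4.06579,50.1432,0.15045,0.178314
4.31434,41.9165,0.152385,0.159302
4.5781,35.0396,0.15424,0.142317
4.85798,29.2909,0.156016,0.127143
5.15496,24.4854,0.157712,0.113587
5.47011,20.4682,0.159327,0.101477
5.80452,17.1101,0.16086,0.0906574
6.15937,14.303,0.162313,0.0809915
6.53592,11.9564,0.163685,0.0723562
6.93549,9.99481,0.164976,0.0646416
7.35949,8.35504,0.166186,0.0577496
7.8094,6.98429,0.167316,0.0515923
8.28683,5.83842,0.168366,0.0460916
8.79343,4.88056,0.169337,0.0411773
9.33101,4.07984,0.17023,0.036787
9.90146,3.41049,0.171044,0.0328648
10.5068,2.85096,0.171781,0.0293608
11.1491,2.38322,0.172442,0.0262303
11.8307,1.99222,0.173025,0.0234337
12.5539,1.66537,0.173534,0.0209352
13.3214,1.39215,0.173967,0.0187031
14.1358,1.16375,0.174326,0.016709
15,0.97282,0.17461,0.0149275
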