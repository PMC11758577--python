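# element=O Z=8 mass=15.999 k_edge_keV=0.5432 l_edge_keV=0.02 kalpha_keV=0.5249 omega_k=0.0083
energy_keV,pe_cm2g,incoh_cm2g,coh_cm2g
0.25,24729.9,0.0296025,3.3036
0.265284,20795.7,0.0311289,3.3036
0.281501,17487.3,0.0327187,3.3036
0.298711,14705.3,0.0343729,3.3036
0.316972,12365.9,0.0360926,3.3036
0.33635,10398.6,0.0378784,3.3036
0.356913,8744.33,0.039731,3.3036
0.378732,7353.22,0.0416505,3.3036
0.401886,6183.41,0.0436373,3.3036
0.426455,5199.7,0.0456911,3.3036
0.452526,4372.5,0.0478116,3.3036
0.48019,3676.89,0.0499982,3.3036
0.509546,3091.94,0.0522499,3.3036
0.540697,2600.05,0.0545656,3.3036
0.5432,2565.22,0.0547484,3.3036
0.5432,26934.8,0.0547484,3.3036
0.573752,22957.3,0.0569436,3.3036
0.608828,19305.1,0.0593822,3.3036
0.646048,16233.9,0.0618792,3.3036
0.685544,13651.3,0.0644322,3.3036
0.727454,11479.5,0.0670382,3.3036
0.771926,9653.28,0.0696942,3.3036
0.819117,8117.56,0.0723967,3.3036
0.869194,6826.16,0.075142,3.3036
0.922331,5740.2,0.0779261,3.3036
0.978717,4827.01,0.0807447,3.3036
1.03855,4059.09,0.0835931,3.07451
1.10204,3413.34,0.0864666,2.74671
1.16941,2870.32,0.0893604,2.45385
1.2409,2413.69,0.0922691,2.19223
1.31677,2029.7,0.0951875,1.95849
1.39727,1706.8,0.0981103,1.74968
1.48269,1435.27,0.101032,1.56313
1.57333,1206.93,0.103947,1.39647
1.66951,1014.93,0.10685,1.24758
1.77158,853.463,0.109736,1.11456
1.87988,717.688,0.112598,0.995727
1.99481,603.512,0.115433,0.889563
2.11676,507.501,0.118234,0.794718
2.24616,426.764,0.120997,0.709985
2.38348,358.871,0.123718,0.634287
2.52919,301.779,0.126391,0.56666
2.68381,253.77,0.129012,0.506243
2.84789,213.398,0.131577,0.452267
3.02199,179.449,0.134084,0.404047
3.20674,150.901,0.136527,0.360967
3.40278,126.894,0.138904,0.322481
3.6108,106.707,0.141213,0.288098
3.83155,89.7313,0.14345,0.257381
4.06579,75.4561,0.145613,0.22994
4.31434,63.452,0.147701,0.205423
4.5781,53.3576,0.149711,0.183521
4.85798,44.869,0.151642,0.163954
5.15496,37.7309,0.153494,0.146474
5.47011,31.7284,0.155264,0.130857
5.80452,26.6808,0.156952,0.116905
6.15937,22.4362,0.158558,0.10444
6.53592,18.8669,0.160081,0.093305
6.93549,15.8654,0.161521,0.0833569
7.35949,13.3414,0.162878,0.0744694
7.8094,11.219,0.164152,0.0665295
8.28683,9.43416,0.165343,0.0594361
8.79343,7.9333,0.166452,0.0530991
9.33101,6.67121,0.167479,0.0474377
9.90146,5.6099,0.168424,0.0423799
10.5068,4.71743,0.169288,0.0378614
11.1491,3.96695,0.170072,0.0338246
11.8307,3.33586,0.170775,0.0302182
12.5539,2.80516,0.171398,0.0269964
13.3214,2.3589,0.171942,0.024118
14.1358,1.98362,0.172408,0.0215466
15,1.66805,0.172795,0.0192493
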