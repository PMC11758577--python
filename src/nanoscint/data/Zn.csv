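# element=Zn Z=30 mass=65.38 k_edge_keV=9.659 l_edge_keV=1.085 kalpha_keV=8.639 omega_k=0.479
energy_keV,pe_cm2g,incoh_cm2g,coh_cm2g
0.25,48517.7,0.00812543,37.3531
0.265284,45722.5,0.0085984,37.3531
0.281501,43088.3,0.00909743,37.3531
0.298711,40605.9,0.0096238,37.3531
0.316972,38266.5,0.0101788,37.3531
0.33635,36061.9,0.0107638,37.3531
0.356913,33984.3,0.0113801,37.3531
0.378732,32026.4,0.0120292,37.3531
0.401886,30181.3,0.0127125,37.3531
0.426455,28442.5,0.0134315,37.3531
0.452526,26803.9,0.0141877,37.3531
0.48019,25259.6,0.0149826,37.3531
0.509546,23804.4,0.0158177,37.3531
0.540697,22432.9,0.0166947,37.3531
0.573752,21140.5,0.017615,37.3531
0.608828,19922.6,0.0185802,37.3531
0.646048,18774.8,0.0195919,37.3531
0.685544,17693.1,0.0206515,37.3531
0.727454,16673.8,0.0217606,37.3531
0.771926,15713.2,0.0229206,37.3531
0.819117,14807.9,0.0241328,37.3531
0.869194,13954.8,0.0253987,37.3531
0.922331,13150.8,0.0267193,37.3531
0.978717,12393.2,0.028096,37.3531
1.03855,11679.2,0.0295297,34.7628
1.10204,10725.3,0.0310213,31.0564
1.16941,9159.23,0.0325717,27.7452
1.2409,7821.86,0.0341814,24.787
1.31677,6679.76,0.0358508,22.1442
1.39727,5704.42,0.0375802,19.7832
1.48269,4871.5,0.0393697,17.6739
1.57333,4160.2,0.041219,15.7895
1.66951,3552.75,0.0431277,14.1061
1.77158,3034,0.0450952,12.6021
1.87988,2591,0.0471204,11.2585
1.99481,2212.68,0.0492021,10.0581
2.11676,1889.59,0.0513388,8.98569
2.24616,1613.69,0.0535286,8.02764
2.38348,1378.07,0.0557694,7.17174
2.52919,1176.85,0.0580587,6.40709
2.68381,1005.02,0.0603937,5.72397
2.84789,858.269,0.0627713,5.11368
3.02199,732.95,0.0651882,4.56846
3.20674,625.93,0.0676406,4.08138
3.40278,534.535,0.0701246,3.64622
3.6108,456.486,0.0726358,3.25746
3.83155,389.833,0.0751698,2.91015
4.06579,332.912,0.0777218,2.59987
4.31434,284.302,0.0802869,2.32268
4.5781,242.79,0.08286,2.07503
4.85798,207.34,0.0854357,1.85379
5.15496,177.065,0.0880086,1.65614
5.47011,151.211,0.0905732,1.47957
5.80452,129.132,0.0931241,1.32181
6.15937,110.277,0.0956555,1.18088
6.53592,94.1754,0.0981619,1.05498
6.93549,80.4245,0.100638,0.942497
7.35949,68.6814,0.103078,0.842008
7.8094,58.653,0.105477,0.752234
8.28683,50.0889,0.107829,0.672031
8.79343,42.7752,0.110129,0.600379
9.33101,36.5295,0.112374,0.536367
9.659,33.3222,0.113652,0.502291
9.659,259.913,0.113652,0.502291
9.90146,243.326,0.114557,0.47918
10.5068,207.797,0.116674,0.42809
11.1491,177.456,0.118722,0.382447
11.8307,151.545,0.120696,0.341671
12.5539,129.417,0.122593,0.305242
13.3214,110.521,0.124409,0.272697
14.1358,94.3832,0.126141,0.243622
15,80.602,0.127786,0.217647
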