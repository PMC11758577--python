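# element=H Z=1 mass=1.008 k_edge_keV=0.0136 l_edge_keV=0 kalpha_keV=0 omega_k=0
energy_keV,pe_cm2g,incoh_cm2g,coh_cm2g
0.25,580.656,0.230829,0.126084
0.265284,477.394,0.236519,0.126084
0.281501,392.496,0.242143,0.126084
0.298711,322.696,0.247693,0.126084
0.316972,265.308,0.253159,0.126084
0.33635,218.127,0.258535,0.126084
0.356913,179.336,0.263812,0.126084
0.378732,147.443,0.268985,0.126084
0.401886,121.222,0.274047,0.126084
0.426455,99.6646,0.278993,0.126084
0.452526,81.9406,0.283818,0.126084
0.48019,67.3685,0.288517,0.126084
0.509546,55.3879,0.293088,0.126084
0.540697,45.5379,0.297527,0.126084
0.573752,37.4396,0.301832,0.126084
0.608828,30.7814,0.306,0.126084
0.646048,25.3074,0.310032,0.126084
0.685544,20.8068,0.313925,0.126084
0.727454,17.1066,0.31768,0.126084
0.771926,14.0644,0.321297,0.126084
0.819117,11.5632,0.324776,0.126084
0.869194,9.50686,0.328118,0.126084
0.922331,7.81619,0.331325,0.126084
0.978717,6.42618,0.334398,0.126084
1.03855,5.28337,0.337339,0.11734
1.10204,4.34379,0.340151,0.10483
1.16941,3.5713,0.342835,0.0936527
1.2409,2.93619,0.345394,0.0836675
1.31677,2.41403,0.347831,0.0747469
1.39727,1.98473,0.350148,0.0667774
1.48269,1.63177,0.352349,0.0596576
1.57333,1.34158,0.354436,0.0532969
1.66951,1.103,0.356412,0.0476144
1.77158,0.906844,0.35828,0.0425378
1.87988,0.745574,0.360043,0.0380024
1.99481,0.612983,0.361704,0.0339506
2.11676,0.503972,0.363266,0.0303308
2.24616,0.414347,0.364731,0.027097
2.38348,0.340661,0.366103,0.0242079
2.52919,0.280079,0.367383,0.0216269
2.68381,0.230271,0.368575,0.019321
2.84789,0.18932,0.369681,0.017261
3.02199,0.155652,0.370704,0.0154207
3.20674,0.127971,0.371645,0.0137765
3.40278,0.105213,0.372506,0.0123077
3.6108,0.0865025,0.37329,0.0109954
3.83155,0.0711191,0.373998,0.0098231
4.06579,0.0584715,0.374632,0.00877576
4.31434,0.0480731,0.375193,0.0078401
4.5781,0.039524,0.375684,0.00700419
4.85798,0.0324951,0.376104,0.0062574
5.15496,0.0267163,0.376455,0.00559024
5.47011,0.0219652,0.376739,0.00499421
5.80452,0.0180589,0.376955,0.00446173
6.15937,0.0148474,0.377104,0.00398602
6.53592,0.012207,0.377187,0.00356104
6.93549,0.0100361,0.377204,0.00318136
7.35949,0.00825134,0.377155,0.00284216
7.8094,0.00678394,0.37704,0.00253913
8.28683,0.00557751,0.37686,0.00226841
8.79343,0.00458562,0.376613,0.00202655
9.33101,0.00377013,0.376299,0.00181048
9.90146,0.00309966,0.375918,0.00161745
10.5068,0.00254843,0.375468,0.001445
11.1491,0.00209522,0.37495,0.00129093
11.8307,0.00172261,0.374361,0.00115329
12.5539,0.00141627,0.373702,0.00103033
13.3214,0.00116441,0.37297,0.000920478
14.1358,0.000957331,0.372164,0.000822337
15,0.000787082,0.371283,0.000734659
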