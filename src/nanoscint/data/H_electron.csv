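energy_keV,stopping_MeVcm2g
0.25,867.041
0.272755,818.116
0.297582,771.425
0.324668,726.92
0.354219,684.548
0.38646,644.251
0.421636,605.967
0.460014,569.634
0.501885,535.184
0.547567,502.551
0.597407,471.665
0.651783,442.459
0.711109,414.863
0.775834,388.808
0.846452,364.227
0.923496,341.054
1.00755,319.222
1.09926,298.668
1.19932,279.328
1.30848,261.142
1.42758,244.052
1.55752,228
1.69928,212.932
1.85395,198.793
2.0227,185.534
2.20681,173.106
2.40768,161.463
2.62683,150.558
2.86592,140.351
3.12678,130.8
3.41138,121.866
3.72189,113.514
4.06066,105.707
4.43026,98.4138
4.83351,91.6021
5.27345,85.2423
5.75345,79.3065
6.27713,73.768
6.84848,68.6019
7.47183,63.7845
8.15193,59.2936
8.89392,55.1083
9.70345,51.2087
10.5867,47.5763
11.5503,44.1936
12.6016,41.0443
13.7486,38.1129
15,35.385
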