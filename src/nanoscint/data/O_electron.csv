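energy_keV,stopping_MeVcm2g
0.25,219.981
0.272755,211.204
0.297582,202.536
0.324668,193.999
0.354219,185.611
0.38646,177.389
0.421636,169.347
0.460014,161.501
0.501885,153.86
0.547567,146.435
0.597407,139.234
0.651783,132.263
0.711109,125.527
0.775834,119.03
0.846452,112.773
0.923496,106.758
1.00755,100.983
1.09926,95.4469
1.19932,90.1478
1.30848,85.082
1.42758,80.2454
1.55752,75.6334
1.69928,71.2406
1.85395,67.0613
2.0227,63.0894
2.20681,59.3185
2.40768,55.7419
2.62683,52.3527
2.86592,49.1441
3.12678,46.109
3.41138,43.2404
3.72189,40.5314
4.06066,37.9749
4.43026,35.5642
4.83351,33.2925
5.27345,31.1532
5.75345,29.1399
6.27713,27.2464
6.84848,25.4665
7.47183,23.7944
8.15193,22.2245
8.89392,20.7512
9.70345,19.3694
10.5867,18.0739
11.5503,16.8599
12.6016,15.7229
13.7486,14.6584
15,13.6621
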