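energy_keV,stopping_MeVcm2g
0.25,237.617
0.272755,227.683
0.297582,217.915
0.324668,208.332
0.354219,198.955
0.38646,189.797
0.421636,180.875
0.460014,172.199
0.501885,163.779
0.547567,155.624
0.597407,147.74
0.651783,140.131
0.711109,132.8
0.775834,125.748
0.846452,118.974
0.923496,112.479
1.00755,106.258
1.09926,100.309
1.19932,94.6271
1.30848,89.2068
1.42758,84.0422
1.55752,79.127
1.69928,74.4542
1.85395,70.0164
2.0227,65.8059
2.20681,61.8151
2.40768,58.0358
2.62683,54.4599
2.86592,51.0794
3.12678,47.8861
3.41138,44.872
3.72189,42.029
4.06066,39.3494
4.43026,36.8256
4.83351,34.4499
5.27345,32.215
5.75345,30.114
6.27713,28.1399
6.84848,26.286
7.47183,24.546
8.15193,22.9137
8.89392,21.3832
9.70345,19.9488
10.5867,18.6052
11.5503,17.347
12.6016,16.1695
13.7486,15.0677
15,14.0374
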