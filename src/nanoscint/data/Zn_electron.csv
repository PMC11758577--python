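energy_keV,stopping_MeVcm2g
0.25,90.5269
0.272755,88.5209
0.297582,86.4491
0.324668,84.3172
0.354219,82.1311
0.38646,79.8972
0.421636,77.6225
0.460014,75.3137
0.501885,72.9779
0.547567,70.6226
0.597407,68.2547
0.651783,65.8816
0.711109,63.5102
0.775834,61.1474
0.846452,58.7998
0.923496,56.4736
1.00755,54.1748
1.09926,51.9089
1.19932,49.6809
1.30848,47.4955
1.42758,45.3567
1.55752,43.2683
1.69928,41.2336
1.85395,39.2551
2.0227,37.3351
2.20681,35.4756
2.40768,33.6778
2.62683,31.9428
2.86592,30.2712
3.12678,28.6633
3.41138,27.1191
3.72189,25.6381
4.06066,24.22
4.43026,22.8637
4.83351,21.5683
5.27345,20.3326
5.75345,19.1553
6.27713,18.0348
6.84848,16.9696
7.47183,15.958
8.15193,14.9982
8.89392,14.0885
9.70345,13.227
10.5867,12.412
11.5503,11.6414
12.6016,10.9135
13.7486,10.2265
15,9.57853
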