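energy_keV,stopping_MeVcm2g
0.25,243.686
0.272755,233.344
0.297582,223.189
0.324668,213.24
0.354219,203.517
0.38646,194.034
0.421636,184.805
0.460014,175.841
0.501885,167.152
0.547567,158.746
0.597407,150.626
0.651783,142.797
0.711109,135.262
0.775834,128.019
0.846452,121.069
0.923496,114.41
1.00755,108.037
1.09926,101.948
1.19932,96.1352
1.30848,90.5944
1.42758,85.3185
1.55752,80.3005
1.69928,75.5328
1.85395,71.0076
2.0227,66.7166
2.20681,62.6515
2.40768,58.8038
2.62683,55.165
2.86592,51.7266
3.12678,48.48
3.41138,45.4169
3.72189,42.529
4.06066,39.8081
4.43026,37.2462
4.83351,34.8356
5.27345,32.5688
5.75345,30.4383
6.27713,28.4372
6.84848,26.5586
7.47183,24.7959
8.15193,23.1428
8.89392,21.5931
9.70345,20.1412
10.5867,18.7815
11.5503,17.5086
12.6016,16.3175
13.7486,15.2034
15,14.1617
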