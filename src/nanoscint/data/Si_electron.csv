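energy_keV,stopping_MeVcm2g
0.25,154.075
0.272755,149.216
0.297582,144.323
0.324668,139.41
0.354219,134.492
0.38646,129.583
0.421636,124.698
0.460014,119.85
0.501885,115.052
0.547567,110.315
0.597407,105.651
0.651783,101.069
0.711109,96.5791
0.775834,92.1894
0.846452,87.9069
0.923496,83.7378
1.00755,79.6875
1.09926,75.7602
1.19932,71.9593
1.30848,68.2874
1.42758,64.7462
1.55752,61.3368
1.69928,58.0594
1.85395,54.9136
2.0227,51.8987
2.20681,49.0131
2.40768,46.2549
2.62683,43.622
2.86592,41.1117
3.12678,38.721
3.41138,36.4468
3.72189,34.2858
4.06066,32.2343
4.43026,30.2887
4.83351,28.4454
5.27345,26.7004
5.75345,25.0499
6.27713,23.4902
6.84848,22.0173
7.47183,20.6275
8.15193,19.317
8.89392,18.0822
9.70345,16.9195
10.5867,15.8253
11.5503,14.7963
12.6016,13.8292
13.7486,12.9206
15,12.0677
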