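energy_keV,stopping_MeVcm2g
0.25,131.977
0.272755,127.975
0.297582,123.932
0.324668,119.86
0.354219,115.773
0.38646,111.682
0.421636,107.6
0.460014,103.538
0.501885,99.5073
0.547567,95.5182
0.597407,91.5807
0.651783,87.7039
0.711109,83.8962
0.775834,80.1653
0.846452,76.5179
0.923496,72.9599
1.00755,69.4966
1.09926,66.1321
1.19932,62.8702
1.30848,59.7135
1.42758,56.6642
1.55752,53.7237
1.69928,50.8927
1.85395,48.1716
2.0227,45.56
2.20681,43.0571
2.40768,40.6618
2.62683,38.3724
2.86592,36.187
3.12678,34.1036
3.41138,32.1195
3.72189,30.2322
4.06066,28.4389
4.43026,26.7365
4.83351,25.1222
5.27345,23.5927
5.75345,22.1449
6.27713,20.7755
6.84848,19.4815
7.47183,18.2596
8.15193,17.1067
8.89392,16.0196
9.70345,14.9953
10.5867,14.0308
11.5503,13.1232
12.6016,12.2697
13.7486,11.4675
15,10.714
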