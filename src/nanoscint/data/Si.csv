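# element=Si Z=14 mass=28.085 k_edge_keV=1.839 l_edge_keV=0.116 kalpha_keV=1.74 omega_k=0.05
energy_keV,pe_cm2g,incoh_cm2g,coh_cm2g
0.25,74129.2,0.018005,9.53711
0.265284,63042.9,0.0189997,9.53711
0.281501,53614.6,0.0200433,9.53711
0.298711,45596.4,0.0211373,9.53711
0.316972,38777.3,0.0222836,9.53711
0.33635,32978,0.0234837,9.53711
0.356913,28046,0.0247392,9.53711
0.378732,23851.7,0.0260518,9.53711
0.401886,20284.6,0.0274229,9.53711
0.426455,17250.9,0.028854,9.53711
0.452526,14671,0.0303463,9.53711
0.48019,12476.9,0.0319011,9.53711
0.509546,10610.9,0.0335195,9.53711
0.540697,9024.04,0.0352024,9.53711
0.573752,7674.46,0.0369506,9.53711
0.608828,6526.72,0.0387647,9.53711
0.646048,5550.63,0.0406451,9.53711
0.685544,4720.51,0.0425919,9.53711
0.727454,4014.54,0.0446052,9.53711
0.771926,3414.15,0.0466846,9.53711
0.819117,2903.56,0.0488295,9.53711
0.869194,2469.32,0.0510391,9.53711
0.922331,2100.02,0.0533123,9.53711
0.978717,1785.96,0.0556476,9.53711
1.03855,1518.86,0.0580432,8.87574
1.10204,1291.71,0.0604971,7.92942
1.16941,1098.53,0.0630067,7.08398
1.2409,934.243,0.0655695,6.32869
1.31677,794.523,0.0681822,5.65393
1.39727,675.7,0.0708415,5.05111
1.48269,574.647,0.0735438,4.51256
1.57333,488.706,0.0762849,4.03144
1.66951,415.619,0.0790606,3.60161
1.77158,353.461,0.0818663,3.2176
1.839,319.196,0.0836457,2.99717
1.839,3287.72,0.0836457,2.99717
1.87988,3096.18,0.0846973,2.87454
1.99481,2633.14,0.0875485,2.56806
2.11676,2239.34,0.0904147,2.29426
2.24616,1904.44,0.0932906,2.04964
2.38348,1619.63,0.0961706,1.83111
2.52919,1377.4,0.0990493,1.63588
2.68381,1171.41,0.101921,1.46146
2.84789,996.221,0.10478,1.30564
3.02199,847.233,0.107621,1.16643
3.20674,720.526,0.110437,1.04207
3.40278,612.769,0.113225,0.930964
3.6108,521.127,0.115978,0.831705
3.83155,443.191,0.11869,0.743029
4.06579,376.91,0.121358,0.663808
4.31434,320.542,0.123976,0.593033
4.5781,272.604,0.12654,0.529804
4.85798,231.835,0.129045,0.473316
5.15496,197.163,0.131487,0.422852
5.47011,167.677,0.133862,0.377767
5.80452,142.6,0.136167,0.33749
6.15937,121.274,0.138399,0.301507
6.53592,103.137,0.140554,0.26936
6.93549,87.7125,0.14263,0.240641
7.35949,74.5948,0.144624,0.214984
7.8094,63.4389,0.146535,0.192063
8.28683,53.9514,0.14836,0.171585
8.79343,45.8828,0.150097,0.153291
9.33101,39.0209,0.151746,0.136947
9.90146,33.1852,0.153305,0.122346
10.5068,28.2222,0.154774,0.109301
11.1491,24.0015,0.15615,0.0976476
11.8307,20.412,0.157435,0.0872364
12.5539,17.3593,0.158626,0.0779353
13.3214,14.7632,0.159725,0.0696259
14.1358,12.5553,0.160731,0.0622024
15,10.6776,0.161643,0.0555704
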