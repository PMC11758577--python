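# element=C Z=6 mass=12.011 k_edge_keV=0.2842 l_edge_keV=0.01 kalpha_keV=0.277 omega_k=0.0028
energy_keV,pe_cm2g,incoh_cm2g,coh_cm2g
0.25,15488.4,0.0375785,1.91064
0.265284,12893.6,0.0394204,1.91064
0.281501,10733.6,0.0413294,1.91064
0.2842,10421.8,0.0416427,1.91064
0.2842,114640,0.0416427,1.91064
0.298711,98289.7,0.0433058,1.91064
0.316972,81823.4,0.0453493,1.91064
0.33635,68115.7,0.0474597,1.91064
0.356913,56704.5,0.0496364,1.91064
0.378732,47204.9,0.0518787,1.91064
0.401886,39296.8,0.0541852,1.91064
0.426455,32713.5,0.0565546,1.91064
0.452526,27233,0.0589851,1.91064
0.48019,22670.8,0.0614746,1.91064
0.509546,18872.8,0.0640208,1.91064
0.540697,15711.1,0.0666208,1.91064
0.573752,13079,0.0692717,1.91064
0.608828,10887.9,0.07197,1.91064
0.646048,9063.89,0.0747122,1.91064
0.685544,7545.44,0.0774942,1.91064
0.727454,6281.37,0.0803119,1.91064
0.771926,5229.06,0.0831607,1.91064
0.819117,4353.05,0.0860361,1.91064
0.869194,3623.79,0.0889331,1.91064
0.922331,3016.71,0.0918465,1.91064
0.978717,2511.33,0.0947714,1.91064
1.03855,2090.61,0.0977022,1.77815
1.10204,1740.37,0.100634,1.58856
1.16941,1448.81,0.10356,1.41919
1.2409,1206.1,0.106477,1.26788
1.31677,1004.04,0.109378,1.1327
1.39727,835.837,0.112258,1.01193
1.48269,695.811,0.115112,0.904036
1.57333,579.243,0.117935,0.807648
1.66951,482.204,0.120722,0.721537
1.77158,401.421,0.123468,0.644607
1.87988,334.172,0.12617,0.575879
1.99481,278.189,0.128822,0.514479
2.11676,231.585,0.13142,0.459626
2.24616,192.788,0.133962,0.410621
2.38348,160.49,0.136443,0.36684
2.52919,133.604,0.138861,0.327728
2.68381,111.221,0.141213,0.292786
2.84789,92.5888,0.143496,0.261569
3.02199,77.0776,0.145709,0.233681
3.20674,64.165,0.147848,0.208766
3.40278,53.4155,0.149913,0.186507
3.6108,44.467,0.151902,0.166622
3.83155,37.0175,0.153814,0.148857
4.06579,30.816,0.155648,0.132986
4.31434,25.6535,0.157404,0.118807
4.5781,21.3558,0.159081,0.10614
4.85798,17.7781,0.160679,0.0948231
5.15496,14.7998,0.162197,0.0847131
5.47011,12.3204,0.163637,0.075681
5.80452,10.2564,0.164997,0.0676119
6.15937,8.53818,0.16628,0.0604032
6.53592,7.1078,0.167484,0.053963
6.93549,5.91704,0.16861,0.0482095
7.35949,4.92577,0.16966,0.0430694
7.8094,4.10057,0.170633,0.0384774
8.28683,3.41361,0.17153,0.0343749
8.79343,2.84174,0.172353,0.0307099
9.33101,2.36567,0.173101,0.0274356
9.90146,1.96935,0.173776,0.0245104
10.5068,1.63943,0.174377,0.0218971
11.1491,1.36478,0.174907,0.0195625
11.8307,1.13614,0.175365,0.0174767
12.5539,0.945806,0.175752,0.0156134
13.3214,0.787357,0.176068,0.0139487
14.1358,0.655453,0.176314,0.0124615
15,0.545647,0.176491,0.0111328
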