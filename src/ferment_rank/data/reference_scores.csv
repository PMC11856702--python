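strain,TTA,Volume,Hardness,Springiness,Score
20,-1.7331,-1.1101,-3.2478,0.0645,-130.0260
35,1.6519,-1.8862,-1.5551,-1.2485,-78.8627
18,-0.2989,-1.2108,0.1840,-1.8004,-68.8262
9,-1.1986,-0.3400,-0.4485,-1.1439,-64.0432
12,-0.7086,-1.4656,0.3489,-0.8521,-57.9189
3,-0.4236,0.6494,-2.0242,0.0391,-37.3833
15,-0.7532,0.5190,-0.6427,-0.7443,-31.4819
28,0.0481,-0.2215,-0.7005,-0.4271,-29.7159
31,0.5830,-2.4312,0.3796,0.5244,-28.1468
36,2.2666,-1.8506,-0.0587,-0.9916,-27.4244
17,-0.7532,-0.4822,0.7423,-0.5064,-18.6429
19,-0.9314,-1.3767,-0.0523,1.6503,-15.0142
27,1.0284,-0.7251,0.4910,-0.8711,-6.8956
5,0.3870,-0.5414,0.6374,-0.6491,-5.5825
29,-1.1986,0.8093,-1.2760,1.2221,-4.4979
8,-0.6641,0.2228,1.0457,-1.0138,-4.1362
4,-1.3768,0.2939,-0.1594,0.9335,-0.6060
13,-0.9314,1.4195,0.1940,-1.0234,0.1765
24,-0.3078,-0.1860,-1.2074,1.8215,1.6870
7,-1.1986,0.9989,0.7666,-0.7696,3.9897
14,-0.3078,-0.2215,0.5645,0.2231,7.0370
10,0.6721,-0.2156,0.7452,-0.6777,9.0823
26,1.9192,0.4183,-1.39233,0.248439,17.06984
32,0.8502,0.1517,0.832254,-0.89015,18.43684
6,0.4315,0.4242,0.740158,-0.573,22.36366
30,0.1198,-0.0971,0.610938,0.502165,24.57858
23,0.9393,0.7619,-0.29574,-0.12263,25.30741
16,-0.6641,0.3531,0.408185,1.165022,31.2823
34,1.2956,0.1162,0.228276,0.080346,32.42902
2,0.3157,0.9219,0.817261,-0.45248,36.63929
22,0.5830,0.3591,0.735874,0.242096,40.89846
21,1.2065,1.4787,-1.05178,0.597312,45.35632
11,0.6810,0.6849,0.724452,0.112062,47.37149
1,-1.0917,1.1470,0.800841,1.421919,57.37611
33,-0.6641,1.3662,1.209204,2.087948,93.81723
25,0.2267,1.2655,0.905788,1.821536,94.30497
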