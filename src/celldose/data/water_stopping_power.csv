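energy_keV,S_keV_per_um
1,11.9776
1.05925,11.5466
1.12202,11.1266
1.1885,10.7175
1.25893,10.3196
1.33352,9.93282
1.41254,9.55721
1.49624,9.19273
1.58489,8.83931
1.6788,8.49686
1.77828,8.16524
1.88365,7.84433
1.99526,7.53398
2.11349,7.23399
2.23872,6.94419
2.37137,6.66438
2.51189,6.39435
2.66073,6.13389
2.81838,5.88276
2.98538,5.64075
3.16228,5.40762
3.34965,5.18314
3.54813,4.96708
3.75837,4.75918
3.98107,4.55923
4.21697,4.36699
4.46684,4.18221
4.73151,4.00467
5.01187,3.83414
5.30884,3.6704
5.62341,3.51322
5.95662,3.36237
6.30957,3.21766
6.68344,3.07886
7.07946,2.94576
7.49894,2.81818
7.94328,2.6959
8.41395,2.57875
8.91251,2.46652
9.44061,2.35904
10,2.25613
10.5925,2.15762
11.2202,2.06334
11.885,1.97312
12.5893,1.88682
13.3352,1.80428
14.1254,1.72534
14.9624,1.64988
15.8489,1.57774
16.788,1.5088
17.7828,1.44292
18.8365,1.37999
19.9526,1.31988
21.1349,1.26248
22.3872,1.20767
23.7137,1.15534
25.1189,1.1054
26.6073,1.05774
28.1838,1.01227
29.8538,0.968897
31.6228,0.927527
33.4965,0.888076
35.4813,0.850464
37.5837,0.814612
39.8107,0.780443
42.1697,0.747884
44.6684,0.716867
47.3151,0.687324
50.1187,0.65919
53.0884,0.632405
56.2341,0.606909
59.5662,0.582646
63.0957,0.559562
66.8344,0.537604
70.7946,0.516723
74.9894,0.496872
79.4328,0.478005
84.1395,0.460078
89.1251,0.443049
94.4061,0.42688
100,0.411532
105.925,0.396968
112.202,0.383153
118.85,0.370055
125.893,0.357642
133.352,0.345883
141.254,0.33475
149.624,0.324214
158.489,0.31425
167.88,0.304832
177.828,0.295936
188.365,0.287539
199.526,0.27962
211.349,0.272157
223.872,0.265131
237.137,0.258521
251.189,0.252312
266.073,0.246484
281.838,0.241021
298.538,0.235907
316.228,0.231128
334.965,0.226669
354.813,0.222516
375.837,0.218655
398.107,0.215075
421.697,0.211762
446.684,0.208705
473.151,0.205894
501.187,0.203316
530.884,0.200963
562.341,0.198823
595.662,0.196888
630.957,0.195148
668.344,0.193594
707.946,0.192217
749.894,0.191011
794.328,0.189965
841.395,0.189074
891.251,0.188329
944.061,0.187722
1000,0.187248
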