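number,entry_name,ri_db,rt_predicted_min,ri_measured,rt_measured_min,deviation_min,suspect
1,Dichlorvos,1248,6.023,1244,6.017,0.006,false
2,Tecnazene,1595,9.618,1597,9.621,0.003,false
3,Diphenylamine,1631,10.007,1592,10.001,0.006,true
4,Chlordimeform,1660,10.319,1661,10.323,0.004,false
5,Trifluralin,1666,10.384,1666,10.380,0.004,false
6,α-BHC,1705,10.803,1707,10.820,0.017,false
7,Hexachlorobenzene,1710,10.856,1709,10.843,0.013,false
8,Pentachloroanisole,1723,10.993,1725,11.009,0.016,false
9,Dicloran,1731,11.077,1731,11.081,0.004,false
10,β-BHC,1755,11.329,1755,11.328,0.001,false
11,Quintozene,1759,11.371,1763,11.373,0.002,false
12,γ-BHC,1769,11.476,1755,11.468,0.008,true
13,Terbufos,1778,11.571,1778,11.571,0.000,false
14,Chlorothalonil,1803,11.833,1803,11.835,0.002,false
15,Tefluthrin,1819,11.996,1818,11.982,0.014,false
16,δ-BHC,1825,12.057,1825,12.055,0.002,false
17,Pentachloraniline,1855,12.363,1858,12.378,0.015,false
18,Chlorpyrifos-methyl,1882,12.638,1883,12.653,0.015,false
19,Vinclozolin,1891,12.730,1857,12.712,0.018,true
20,Parathion-methyl,1896,12.781,1895,12.770,0.011,false
21,Heptachlor,1909,12.910,1915,12.927,0.017,false
22,Fenchlorphos,1916,12.979,1918,12.995,0.016,false
23,Octachlorodipropylether,1932,13.136,1932,13.140,0.004,false
24,Fenitrothion,1946,13.273,1945,13.267,0.006,false
25,Methyl-pentachlorophenyl sulfide,1954,13.351,1957,13.365,0.014,false
26,Dichlofluanid,1959,13.400,1960,13.410,0.010,false
27,Chlorpyrifos,1977,13.577,1978,13.583,0.006,false
28,Aldrin,1981,13.601,1964,13.595,0.006,true
29,Fenthion-d6,1982,13.626,1981,13.616,0.010,false
30,Chlorthal-dimethyl,1986,13.665,1988,13.677,0.012,false
31,Parathion-ethyl,1993,13.734,1993,13.730,0.004,false
32,Triadimefon,1999,13.793,1999,13.793,0.000,false
33,Dicofol,2008,13.878,2009,13.889,0.011,false
34,Butralin,2012,13.935,2014,13.938,0.003,false
35,Bromophos-methyl,2021,14.012,2023,14.018,0.006,false
36,Pendimethalin,2044,14.227,2046,14.232,0.005,false
37,Fipronil,2055,14.321,2054,14.314,0.007,false
38,Heptachlor exo-epoxide,2061,14.397,2067,14.401,0.004,false
39,Chlordane-oxy,2061,14.398,2067,14.409,0.011,false
40,Heptachlor endo-epoxide,2069,14.453,2075,14.468,0.015,false
41,Dimepiperate,2086,14.613,2087,14.622,0.009,false
42,Procymidone,2086,14.613,2086,14.617,0.004,false
43,Triadimenol-1,2087,14.622,2086,14.617,0.005,false
44,Triadimenol-2,2103,14.772,2103,14.768,0.004,false
45,Bromophos-ethyl,2106,14.799,2109,14.812,0.013,false
46,Chlordane-trans,2110,14.835,2108,14.817,0.018,false
47,"o,p'-DDE",2116,14.889,2120,14.905,0.016,false
48,Flumetralin,2127,14.989,2128,14.994,0.005,false
49,Chlordane-cis,2137,15.079,2144,15.081,0.002,false
50,α-Endosulfan,2139,15.098,2144,15.105,0.007,false
51,"p,p'-DDE",2185,15.514,2188,15.524,0.010,false
52,Dieldrin,2195,15.604,2175,15.601,0.003,true
53,"o,p'-DDD",2199,15.640,2224,15.655,0.015,true
54,Chlorfenapyr,2222,15.841,2222,15.837,0.004,false
55,Nitrofen,2239,15.969,2213,15.965,0.004,true
56,Endrin,2240,15.997,2247,16.011,0.014,false
57,β-Endosulfan,2266,16.223,2270,16.239,0.016,false
58,"p,p'-DDD",2276,16.310,2299,16.312,0.002,true
59,"o,p'-DDT",2280,16.345,2259,16.361,0.016,true
60,Endosulfan sulfate,2351,16.945,2355,16.958,0.013,false
61,"p,p'-DDT",2359,17.032,2364,17.040,0.008,false
62,Bifenthrin,2469,17.909,2469,17.908,0.001,false
63,Bromopropylate,2475,17.957,2438,17.951,0.006,true
64,Methoxychlor,2487,18.043,2460,18.036,0.007,true
65,Fenpropathrin,2493,18.101,2492,18.096,0.005,false
66,Phenothrin-1,2526,18.359,2526,18.362,0.003,false
67,Phenothrin-2,2540,18.467,2541,18.473,0.006,false
68,Cyhalothrin-1,2573,18.722,2572,18.713,0.009,false
69,Acrinathrin,2591,18.861,2595,18.871,0.010,false
70,Cyhalothrin-2,2595,18.892,2595,18.891,0.001,false
71,Mirex,2610,19.005,2615,19.014,0.009,false
72,Acrinathrin-2,2619,19.062,2616,19.052,0.010,false
73,Permethrin-1,2702,19.696,2703,19.701,0.005,false
74,Permethrin-2,2720,19.821,2721,19.828,0.007,false
75,Cyfluthrin-1,2777,20.232,2778,20.236,0.004,false
76,Cyfluthrin-2,2791,20.333,2791,20.334,0.001,false
77,Cyfluthrin-3,2799,20.390,2800,20.395,0.005,false
78,Cyfluthrin-4,2806,20.439,2806,20.439,0.000,false
79,Cypermethrin-1,2823,20.557,2824,20.561,0.004,false
80,Cypermethrin-2,2838,20.662,2824,20.663,0.001,true
81,Cypermethrin-3,2845,20.711,2847,20.717,0.006,false
82,Flucythrinate-1,2847,20.724,2847,20.726,0.002,false
83,Quizalofop-ethyl,2848,20.743,2851,20.751,0.008,false
84,Cypermethrin-4,2852,20.759,2852,20.762,0.003,false
85,Flucythrinate-2,2875,20.919,2875,20.922,0.003,false
86,Fenvalerate-1,2951,21.442,2930,21.448,0.006,true
87,Fenvalerate-2,2981,21.628,2930,21.619,0.009,true
88,Deltamethrin-1,3031,22.016,3034,22.024,0.008,false
89,Deltamethrin-2,3060,22.235,3063,22.242,0.007,false
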