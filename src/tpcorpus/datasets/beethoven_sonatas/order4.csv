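piece_index,"0,-1,-3,-5,-6","0,-2,-3,-5,-7","0,-2,-4,-5,-7"
1,0.380,0.567,0.695
2,0.500,0.739,0.650
3,0.475,0.712,0.675
4,0.609,0.696,0.360
5,0.535,0.356,0.729
6,0.353,0.740,0.473
7,0.296,0.493,0.448
8,0.754,0.507,0.593
9,0.585,0.648,0.485
10,0.370,0.717,0.531
11,0.380,0.567,0.695
12,0.431,0.907,0.727
13,0.455,0.607,0.281
14,0.133,0.667,0.167
15,0.458,0.702,0.603
16,0.322,0.813,0.522
17,0.536,0.048,0.792
18,0.487,0.556,0.491
19,0.357,0.417,0.533
20,0.281,0.788,0.710
21,0.571,0.537,0.580
22,0.438,0.571,0.500
23,0.404,0.333,0.603
24,0.600,0.571,0.419
25,0.682,0.489,0.559
26,0.508,0.743,0.700
27,0.410,0.476,0.575
28,0.243,0.200,0.238
29,0.369,0.654,0.504
30,0.467,0.556,0.268
31,0.167,0.160,0.227
32,0.565,0.114,0.130
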