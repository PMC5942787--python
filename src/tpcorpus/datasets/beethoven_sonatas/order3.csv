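piece_index,"0,-1,-3,-5","0,-1,0,-1","0,-1,0,2","0,-2,-3,-2","0,-2,-3,-5","0,-2,-4,-5","0,0,0,0","0,1,3,1","0,1,3,5","0,2,0,-1","0,2,3,5","0,2,4,5"
1,0.385,0.186,0.342,0.311,0.437,0.609,0.421,0.360,0.220,0.346,0.347,0.692
2,0.723,0.179,0.250,0.140,0.588,0.609,0.435,0.177,0.554,0.689,0.484,0.650
3,0.631,0.138,0.351,0.376,0.471,0.574,0.500,0.220,0.372,0.407,0.348,0.607
4,0.592,0.220,0.190,0.348,0.312,0.665,0.387,0.236,0.439,0.484,0.353,0.407
5,0.355,0.080,0.193,0.213,0.471,0.579,0.308,0.288,0.500,0.453,0.625,0.523
6,0.553,0.263,0.298,0.236,0.338,0.532,0.582,0.470,0.120,0.474,0.319,0.535
7,0.403,0.099,0.249,0.245,0.351,0.429,0.679,0.298,0.351,0.600,0.280,0.449
8,0.439,0.150,0.475,0.199,0.414,0.647,0.507,0.340,0.180,0.345,0.117,0.250
9,0.644,0.163,0.244,0.191,0.412,0.667,0.780,0.200,0.520,0.500,0.333,0.556
10,0.514,0.250,0.398,0.313,0.343,0.471,0.563,0.086,0.633,0.622,0.461,0.762
11,0.594,0.318,0.259,0.288,0.479,0.663,0.400,0.161,0.427,0.270,0.297,0.568
12,0.785,0.356,0.178,0.183,0.606,0.611,0.788,0.036,0.309,0.047,0.193,0.674
13,0.677,0.456,0.222,0.221,0.295,0.564,0.710,0.132,0.679,0.455,0.429,0.639
14,0.242,0.200,0.333,0.070,0.349,0.136,0.644,0.063,0.708,0.206,0.755,0.615
15,0.673,0.253,0.222,0.201,0.582,0.624,0.586,0.379,0.221,0.346,0.353,0.644
16,0.732,0.107,0.348,0.554,0.338,0.390,0.758,0.427,0.266,0.415,0.225,0.467
17,0.394,0.429,0.112,0.277,0.323,0.615,0.261,0.197,0.242,0.176,0.349,0.655
18,0.506,0.227,0.464,0.342,0.375,0.731,0.782,0.129,0.548,0.393,0.483,0.567
19,0.509,0.033,0.154,0.247,0.444,0.508,0.460,0.214,0.333,0.313,0.275,0.419
20,0.727,0.333,0.148,0.136,0.500,0.425,0.206,0.091,0.773,0.207,0.640,0.467
21,0.424,0.215,0.301,0.395,0.469,0.595,0.759,0.177,0.310,0.294,0.316,0.575
22,0.571,0.147,0.147,0.549,0.412,0.545,0.788,0.490,0.429,0.302,0.413,0.462
23,0.435,0.318,0.288,0.274,0.523,0.438,0.592,0.417,0.135,0.505,0.303,0.333
24,0.563,0.113,0.227,0.364,0.318,0.566,0.571,0.078,0.216,0.382,0.209,0.154
25,0.595,0.044,0.156,0.191,0.500,0.656,0.048,0.188,0.313,0.074,0.271,0.407
26,0.700,0.301,0.252,0.159,0.536,0.635,0.611,0.155,0.700,0.192,0.598,0.579
27,0.406,0.162,0.132,0.149,0.634,0.533,0.561,0.367,0.233,0.355,0.171,0.100
28,0.552,0.101,0.275,0.375,0.278,0.296,0.365,0.188,0.446,0.303,0.486,0.532
29,0.533,0.157,0.220,0.281,0.343,0.504,0.531,0.284,0.279,0.245,0.404,0.515
30,0.600,0.149,0.338,0.185,0.196,0.500,0.560,0.130,0.435,0.169,0.427,0.456
31,0.364,0.256,0.487,0.272,0.272,0.611,0.557,0.239,0.304,0.175,0.318,0.429
32,0.324,0.319,0.353,0.444,0.222,0.509,0.471,0.462,0.146,0.482,0.273,0.443
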