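piece_index,"0,-5,0","0,-4,-5","0,-3,-5","0,-3,-2","0,-2,-4","0,-2,-3","0,-2,-2","0,-2,0","0,-2,2","0,-2,5","0,-1,-3","0,-1,-1","0,-1,0","0,-1,2","0,0,-2","0,0,-1","0,0,0","0,0,1","0,0,2","0,0,3","0,0,5","0,1,-4","0,1,-2","0,1,-1","0,1,0","0,1,1","0,1,3","0,2,0","0,2,3","0,2,4","0,3,0","0,3,1","0,3,2","0,3,3","0,4,2","0,4,7","0,5,9"
1,0.035,0.035,0.026,0.080,0.247,0.351,0.079,0.139,0.016,0.016,0.397,0.052,0.314,0.033,0.151,0.166,0.337,0.036,0.068,0.056,0.044,0.017,0.088,0.008,0.237,0.052,0.275,0.326,0.224,0.161,0.045,0.309,0.197,0.096,0.077,0.359,0.109
2,0.127,0.037,0.044,0.104,0.361,0.358,0.042,0.041,0.019,0.009,0.462,0.087,0.192,0.076,0.058,0.092,0.425,0.089,0.049,0.070,0.028,0.037,0.017,0.025,0.110,0.040,0.217,0.122,0.344,0.333,0.018,0.301,0.147,0.086,0.150,0.478,0.311
3,0.022,0.086,0.074,0.123,0.304,0.322,0.025,0.153,0.028,0.009,0.292,0.067,0.431,0.034,0.153,0.437,0.218,0.105,0.009,0.009,0.031,0.033,0.113,0.023,0.192,0.060,0.246,0.201,0.308,0.237,0.066,0.095,0.079,0.021,0.088,0.302,0.180
4,0.120,0.063,0.059,0.189,0.241,0.366,0.105,0.056,0.026,0.007,0.254,0.061,0.346,0.163,0.142,0.211,0.350,0.039,0.022,0.051,0.010,0.023,0.037,0.028,0.118,0.048,0.180,0.225,0.164,0.196,0.133,0.232,0.058,0.019,0.130,0.178,0.218
5,0.200,0.067,0.045,0.083,0.279,0.357,0.065,0.041,0.014,0.046,0.346,0.049,0.251,0.083,0.115,0.182,0.252,0.057,0.073,0.035,0.035,0.011,0.037,0.015,0.075,0.060,0.247,0.268,0.242,0.328,0.067,0.233,0.193,0.040,0.118,0.235,0.057
6,0.138,0.101,0.026,0.171,0.290,0.309,0.113,0.067,0.015,0.044,0.330,0.099,0.306,0.161,0.040,0.125,0.509,0.070,0.114,0.006,0.042,0.065,0.062,0.024,0.173,0.078,0.270,0.320,0.238,0.142,0.110,0.280,0.022,0.038,0.271,0.086,0.056
7,0.033,0.096,0.121,0.102,0.261,0.348,0.085,0.048,0.027,0.030,0.322,0.038,0.332,0.049,0.124,0.162,0.379,0.059,0.048,0.028,0.045,0.026,0.037,0.014,0.086,0.067,0.166,0.263,0.282,0.184,0.044,0.213,0.088,0.013,0.066,0.166,0.157
8,0.060,0.235,0.122,0.122,0.271,0.369,0.120,0.061,0.012,0.014,0.339,0.073,0.186,0.071,0.174,0.249,0.257,0.064,0.117,0.008,0.042,0.025,0.058,0.025,0.089,0.100,0.277,0.197,0.378,0.177,0.370,0.162,0.078,0.019,0.057,0.092,0.081
9,0.027,0.050,0.010,0.038,0.330,0.424,0.049,0.065,0.013,0.016,0.353,0.024,0.301,0.105,0.014,0.149,0.577,0.028,0.060,0.005,0.028,0.044,0.006,0.034,0.088,0.106,0.156,0.134,0.384,0.274,0.115,0.204,0.124,0.027,0.130,0.145,0.022
10,0.014,0.074,0.125,0.197,0.244,0.316,0.112,0.059,0.019,0.016,0.382,0.087,0.320,0.044,0.170,0.134,0.404,0.032,0.036,0.018,0.029,0.050,0.036,0.028,0.084,0.062,0.279,0.125,0.393,0.409,0.073,0.236,0.491,0.018,0.320,0.160,0.021
11,0.217,0.067,0.075,0.048,0.288,0.316,0.046,0.129,0.022,0.013,0.291,0.038,0.516,0.028,0.162,0.162,0.168,0.117,0.140,0.067,0.022,0.046,0.067,0.024,0.198,0.022,0.189,0.206,0.319,0.273,0.118,0.179,0.087,0.004,0.097,0.306,0.244
12,0.320,0.130,0.016,0.109,0.280,0.220,0.059,0.227,0.006,0.006,0.270,0.137,0.303,0.008,0.037,0.078,0.663,0.058,0.014,0.010,0.023,0.007,0.067,0.060,0.142,0.149,0.205,0.271,0.242,0.195,0.354,0.062,0.062,0.062,0.140,0.107,0.057
13,0.149,0.090,0.187,0.043,0.326,0.306,0.061,0.035,0.048,0.016,0.273,0.059,0.378,0.113,0.075,0.109,0.547,0.015,0.026,0.030,0.026,0.062,0.044,0.022,0.220,0.093,0.233,0.058,0.368,0.437,0.317,0.174,0.096,0.030,0.055,0.315,0.105
14,0.393,0.055,0.022,0.045,0.190,0.186,0.121,0.152,0.009,0.013,0.383,0.173,0.093,0.080,0.016,0.101,0.474,0.035,0.019,0.044,0.052,0.018,0.043,0.030,0.098,0.037,0.293,0.157,0.245,0.301,0.026,0.055,0.035,0.040,0.011,0.242,0.157
15,0.076,0.119,0.064,0.165,0.335,0.394,0.058,0.039,0.005,0.025,0.331,0.031,0.310,0.122,0.075,0.180,0.418,0.049,0.042,0.020,0.042,0.039,0.116,0.020,0.217,0.092,0.208,0.214,0.350,0.185,0.060,0.352,0.086,0.004,0.147,0.431,0.319
16,0.228,0.113,0.061,0.165,0.256,0.321,0.041,0.093,0.068,0.004,0.220,0.020,0.452,0.070,0.040,0.135,0.501,0.027,0.036,0.009,0.007,0.068,0.072,0.016,0.113,0.057,0.195,0.376,0.228,0.235,0.160,0.321,0.153,0.059,0.203,0.211,0.129
17,0.142,0.010,0.044,0.120,0.162,0.270,0.220,0.008,0.017,0.012,0.167,0.104,0.379,0.016,0.124,0.162,0.124,0.143,0.038,0.054,0.011,0.023,0.046,0.005,0.190,0.181,0.151,0.111,0.281,0.190,0.118,0.034,0.034,0.050,0.026,0.123,0.090
18,0.074,0.059,0.066,0.189,0.199,0.306,0.071,0.036,0.087,0.005,0.284,0.030,0.362,0.074,0.067,0.040,0.325,0.056,0.016,0.078,0.102,0.072,0.030,0.008,0.089,0.065,0.295,0.168,0.245,0.287,0.269,0.138,0.034,0.061,0.137,0.133,0.188
19,0.148,0.361,0.133,0.083,0.251,0.345,0.119,0.149,0.009,0.004,0.270,0.054,0.446,0.108,0.103,0.179,0.342,0.087,0.022,0.033,0.092,0.065,0.112,0.014,0.093,0.056,0.195,0.101,0.323,0.272,0.071,0.464,0.089,0.196,0.256,0.179,0.052
20,0.256,0.050,0.260,0.078,0.227,0.206,0.115,0.097,0.009,0.040,0.328,0.187,0.201,0.037,0.161,0.082,0.382,0.064,0.061,0.021,0.014,0.025,0.062,0.086,0.148,0.259,0.272,0.181,0.156,0.281,0.186,0.339,0.153,0.085,0.094,0.688,0.300
21,0.119,0.104,0.063,0.057,0.259,0.334,0.012,0.056,0.030,0.004,0.378,0.005,0.419,0.077,0.026,0.029,0.529,0.036,0.049,0.016,0.021,0.038,0.062,0.038,0.203,0.032,0.243,0.186,0.346,0.232,0.333,0.086,0.099,0.036,0.168,0.220,0.213
22,0.211,0.010,0.016,0.219,0.221,0.256,0.010,0.241,0.030,0.005,0.155,0.028,0.641,0.028,0.008,0.050,0.661,0.021,0.008,0.017,0.033,0.020,0.234,0.051,0.153,0.047,0.166,0.232,0.202,0.228,0.056,0.100,0.061,0.017,0.039,0.455,0.089
23,0.257,0.114,0.047,0.107,0.243,0.329,0.015,0.195,0.026,0.022,0.382,0.030,0.234,0.064,0.055,0.069,0.547,0.040,0.024,0.024,0.014,0.119,0.104,0.018,0.272,0.056,0.244,0.538,0.168,0.091,0.159,0.020,0.022,0.022,0.048,0.273,0.161
24,0.234,0.082,0.052,0.060,0.239,0.346,0.057,0.088,0.025,0.016,0.252,0.025,0.344,0.064,0.048,0.043,0.080,0.027,0.059,0.207,0.053,0.070,0.056,0.007,0.178,0.021,0.178,0.239,0.187,0.113,0.211,0.058,0.063,0.126,0.261,0.136,0.087
25,0.341,0.082,0.077,0.138,0.278,0.290,0.034,0.130,0.025,0.025,0.411,0.056,0.250,0.117,0.147,0.015,0.309,0.074,0.059,0.132,0.044,0.103,0.085,0.006,0.194,0.067,0.194,0.324,0.201,0.294,0.293,0.044,0.073,0.015,0.053,0.140,0.118
26,0.031,0.365,0.182,0.045,0.288,0.315,0.053,0.094,0.016,0.034,0.218,0.068,0.347,0.119,0.136,0.127,0.245,0.068,0.055,0.041,0.018,0.068,0.068,0.010,0.184,0.045,0.355,0.221,0.279,0.324,0.123,0.167,0.148,0.086,0.098,0.244,0.133
27,0.121,0.314,0.091,0.015,0.243,0.327,0.136,0.068,0.029,0.026,0.331,0.137,0.232,0.017,0.125,0.103,0.303,0.052,0.063,0.033,0.066,0.006,0.025,0.006,0.148,0.093,0.185,0.252,0.285,0.163,0.253,0.207,0.184,0.103,0.321,0.075,0.037
28,0.025,0.152,0.171,0.144,0.193,0.196,0.125,0.280,0.005,0.005,0.207,0.127,0.214,0.025,0.165,0.176,0.230,0.057,0.087,0.022,0.030,0.066,0.060,0.006,0.160,0.038,0.352,0.154,0.292,0.282,0.078,0.149,0.045,0.065,0.082,0.286,0.108
29,0.130,0.163,0.095,0.098,0.273,0.299,0.096,0.108,0.034,0.003,0.298,0.098,0.207,0.072,0.099,0.110,0.269,0.049,0.063,0.026,0.050,0.028,0.036,0.027,0.142,0.081,0.286,0.217,0.292,0.247,0.123,0.185,0.080,0.164,0.149,0.109,0.085
30,0.232,0.050,0.035,0.126,0.242,0.271,0.077,0.218,0.009,0.018,0.205,0.094,0.307,0.070,0.070,0.120,0.291,0.089,0.062,0.023,0.031,0.025,0.079,0.028,0.142,0.054,0.290,0.224,0.259,0.243,0.288,0.144,0.064,0.048,0.256,0.067,0.104
31,0.266,0.023,0.055,0.105,0.187,0.238,0.054,0.223,0.018,0.016,0.276,0.046,0.163,0.075,0.114,0.145,0.405,0.064,0.123,0.023,0.041,0.020,0.132,0.020,0.113,0.066,0.305,0.176,0.194,0.154,0.075,0.345,0.144,0.029,0.207,0.146,0.060
32,0.126,0.100,0.070,0.098,0.170,0.317,0.053,0.166,0.032,0.013,0.262,0.065,0.376,0.077,0.114,0.133,0.369,0.084,0.044,0.019,0.049,0.023,0.029,0.027,0.260,0.061,0.273,0.386,0.181,0.192,0.095,0.167,0.145,0.091,0.190,0.216,0.093
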