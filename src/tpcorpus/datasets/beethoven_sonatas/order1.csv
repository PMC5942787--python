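piece_index,"0,-12","0,-9","0,-7","0,-6","0,-5","0,-4","0,-3","0,-2","0,-1","0,0","0,1","0,2","0,3","0,4","0,5","0,6","0,7","0,8","0,9","0,12"
1,0.004,0.008,0.017,0.011,0.032,0.032,0.078,0.180,0.147,0.096,0.104,0.092,0.051,0.022,0.034,0.006,0.021,0.023,0.015,0.004
2,0.016,0.006,0.007,0.006,0.019,0.029,0.050,0.175,0.120,0.090,0.164,0.101,0.045,0.031,0.033,0.007,0.019,0.013,0.008,0.019
3,0.029,0.013,0.015,0.009,0.025,0.034,0.064,0.125,0.116,0.042,0.122,0.082,0.044,0.037,0.037,0.010,0.015,0.009,0.021,0.067
4,0.032,0.014,0.014,0.017,0.022,0.030,0.056,0.120,0.100,0.071,0.119,0.072,0.084,0.048,0.040,0.022,0.019,0.020,0.015,0.018
5,0.026,0.004,0.006,0.008,0.026,0.028,0.050,0.163,0.131,0.118,0.100,0.074,0.056,0.019,0.033,0.018,0.027,0.019,0.015,0.033
6,0.027,0.022,0.019,0.005,0.030,0.025,0.039,0.123,0.096,0.160,0.095,0.078,0.047,0.018,0.027,0.007,0.018,0.006,0.013,0.080
7,0.013,0.007,0.016,0.008,0.031,0.042,0.040,0.151,0.138,0.074,0.144,0.067,0.040,0.046,0.032,0.009,0.013,0.016,0.022,0.022
8,0.050,0.006,0.016,0.006,0.021,0.025,0.053,0.150,0.134,0.081,0.111,0.090,0.047,0.027,0.042,0.009,0.020,0.012,0.009,0.029
9,0.012,0.006,0.011,0.017,0.034,0.046,0.049,0.143,0.132,0.100,0.148,0.076,0.052,0.032,0.043,0.010,0.010,0.018,0.014,0.014
10,0.003,0.009,0.015,0.013,0.027,0.043,0.055,0.154,0.099,0.100,0.179,0.129,0.020,0.009,0.017,0.006,0.015,0.010,0.016,0.031
11,0.010,0.007,0.013,0.017,0.029,0.030,0.092,0.140,0.108,0.036,0.153,0.087,0.046,0.029,0.031,0.013,0.012,0.016,0.019,0.047
12,0.016,0.021,0.020,0.014,0.030,0.024,0.077,0.100,0.075,0.160,0.083,0.073,0.060,0.037,0.060,0.012,0.015,0.022,0.024,0.015
13,0.005,0.013,0.018,0.019,0.054,0.051,0.098,0.109,0.084,0.093,0.080,0.067,0.059,0.026,0.033,0.014,0.019,0.021,0.049,0.006
14,0.010,0.023,0.035,0.012,0.048,0.029,0.043,0.074,0.052,0.118,0.052,0.069,0.111,0.061,0.082,0.020,0.027,0.022,0.014,0.018
15,0.020,0.002,0.007,0.002,0.019,0.033,0.061,0.182,0.156,0.075,0.112,0.059,0.065,0.025,0.029,0.007,0.014,0.010,0.017,0.038
16,0.034,0.003,0.013,0.013,0.034,0.046,0.057,0.142,0.115,0.091,0.131,0.080,0.059,0.049,0.029,0.008,0.008,0.016,0.007,0.037
17,0.039,0.017,0.017,0.015,0.028,0.028,0.060,0.064,0.113,0.098,0.116,0.041,0.070,0.041,0.038,0.018,0.017,0.023,0.014,0.063
18,0.013,0.011,0.024,0.009,0.046,0.042,0.079,0.088,0.061,0.124,0.119,0.082,0.093,0.054,0.042,0.004,0.020,0.012,0.011,0.007
19,0.002,0.010,0.012,0.016,0.018,0.025,0.041,0.161,0.139,0.126,0.147,0.108,0.038,0.027,0.040,0.004,0.018,0.012,0.007,0.014
20,0.001,0.015,0.007,0.004,0.024,0.024,0.046,0.193,0.081,0.169,0.049,0.096,0.036,0.019,0.018,0.007,0.018,0.010,0.017,0.005
21,0.017,0.005,0.014,0.012,0.045,0.062,0.110,0.121,0.095,0.060,0.102,0.071,0.082,0.050,0.045,0.008,0.012,0.010,0.011,0.026
22,0.019,0.022,0.072,0.026,0.017,0.030,0.057,0.058,0.053,0.071,0.087,0.067,0.053,0.045,0.049,0.048,0.034,0.036,0.042,0.027
23,0.025,0.012,0.012,0.012,0.042,0.048,0.086,0.122,0.094,0.084,0.066,0.066,0.107,0.062,0.054,0.013,0.016,0.015,0.014,0.022
24,0.005,0.015,0.025,0.044,0.036,0.041,0.084,0.108,0.096,0.064,0.097,0.078,0.076,0.030,0.043,0.008,0.018,0.019,0.037,0.025
25,0.015,0.022,0.034,0.010,0.052,0.066,0.070,0.124,0.069,0.026,0.064,0.112,0.079,0.066,0.066,0.008,0.031,0.007,0.021,0.019
26,0.025,0.008,0.013,0.004,0.032,0.038,0.066,0.145,0.136,0.073,0.103,0.109,0.054,0.014,0.032,0.012,0.016,0.016,0.015,0.044
27,0.012,0.007,0.019,0.010,0.031,0.027,0.035,0.165,0.156,0.144,0.087,0.066,0.046,0.028,0.029,0.022,0.018,0.020,0.008,0.019
28,0.011,0.010,0.027,0.013,0.027,0.015,0.049,0.123,0.108,0.123,0.107,0.164,0.051,0.033,0.050,0.006,0.011,0.013,0.013,0.012
29,0.004,0.008,0.017,0.011,0.032,0.032,0.078,0.180,0.147,0.096,0.104,0.092,0.051,0.022,0.034,0.006,0.021,0.023,0.015,0.004
30,0.012,0.009,0.016,0.010,0.021,0.046,0.088,0.128,0.093,0.098,0.121,0.141,0.047,0.034,0.029,0.015,0.012,0.016,0.020,0.009
31,0.024,0.008,0.027,0.010,0.038,0.035,0.073,0.156,0.097,0.090,0.061,0.092,0.070,0.033,0.061,0.006,0.020,0.021,0.010,0.025
32,0.011,0.004,0.015,0.015,0.030,0.035,0.054,0.157,0.136,0.108,0.120,0.092,0.069,0.029,0.027,0.011,0.016,0.012,0.013,0.011
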