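item,univariate_entropy,rho1,rho2,rho3,rho4,rho5
4,0.169,0.45,0.54,0.06,0.91,0.06
5,0.146,0.42,0.62,0.07,0.75,0.02
6,0.084,0.51,0.65,0.20,0.65,0.13
7,0.126,0.65,0.28,0.02,0.06,0.05
8,0.063,0.54,0.59,0.32,0.25,0.11
10,0.075,0.14,0.24,0.03,0.39,0.01
14,0.127,0.55,0.01,0.00,0.07,0.01
15,0.168,0.65,0.01,0.00,0.00,0.02
16,0.162,0.67,0.03,0.00,0.03,0.01
17,0.182,0.84,0.01,0.02,0.18,0.08
19,0.093,0.50,0.43,0.04,0.07,0.08
22,0.067,0.37,0.46,0.14,0.10,0.03
24,0.067,0.19,0.40,0.10,0.04,0.00
37,0.041,0.17,0.21,0.07,0.04,0.02
39,0.037,0.10,0.19,0.05,0.04,0.02
40,0.043,0.13,0.38,0.17,0.08,0.08
33,0.049,0.12,0.37,0.10,0.08,0.02
36,0.036,0.93,0.94,0.85,0.83,0.73
59,0.041,0.17,0.27,0.07,0.04,0.03
61,0.039,0.34,0.68,0.45,0.45,0.36
65,0.039,0.15,0.32,0.10,0.09,0.07
42,0.154,0.73,0.06,0.04,0.02,0.02
43,0.112,0.56,0.04,0.05,0.02,0.01
44,0.175,0.88,0.90,0.95,0.57,0.06
45,0.124,0.76,0.91,0.86,0.53,0.16
46,0.048,0.41,0.47,0.40,0.22,0.11
47,0.072,0.14,0.43,0.10,0.00,0.02
48,0.075,0.17,0.45,0.13,0.01,0.00
49,0.038,0.95,0.90,0.92,0.81,0.75
50,0.060,0.22,0.45,0.28,0.05,0.07
51,0.039,0.71,0.87,0.75,0.61,0.55
52,0.053,0.81,0.83,0.69,0.62,0.40
56,0.037,0.73,0.80,0.71,0.49,0.61
57,0.041,0.14,0.24,0.04,0.06,0.04
68,0.033,0.21,0.28,0.15,0.25,0.07
74,0.033,0.82,0.62,0.64,0.73,0.57
78,0.030,0.20,0.36,0.23,0.20,0.15
85,0.033,0.36,0.64,0.40,0.36,0.37
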