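BA,Kin,NAA,GA3,SN,SL,CW,SE_SN,SE_SL,SE_CW,NREP
0,0,0,0,0.00,0.00,0.00,0.000,0.000,0.000,4
0,0,0,0.2,0.00,0.00,0.00,0.000,0.000,0.000,4
0,0,0.1,0,0.00,0.00,0.00,0.000,0.000,0.000,4
0,0,0.1,0.2,0.38,0.23,0.00,0.180,0.104,0.000,4
0,0.5,0,0,1.37,1.79,0.00,0.125,0.006,0.000,4
0,0.5,0,0.2,2.38,1.96,0.00,0.125,0.004,0.000,4
0,0.5,0.1,0,2.25,1.94,0.00,0.171,0.003,0.000,4
0,0.5,0.1,0.2,2.50,2.19,0.00,0.158,0.006,0.000,4
0,1,0,0,2.69,2.55,0.00,0.176,0.007,0.000,4
0,1,0,0.2,2.94,2.76,0.00,0.193,0.012,0.000,4
0,1,0.1,0,3.00,2.68,0.00,0.224,0.007,0.000,4
0,1,0.1,0.2,3.19,2.89,0.01,0.164,0.007,0.003,4
0,2,0,0,4.38,3.28,0.04,0.180,0.004,0.002,4
0,2,0,0.2,4.56,3.43,0.05,0.128,0.005,0.002,4
0,2,0.1,0,4.38,3.37,0.06,0.155,0.004,0.002,4
0,2,0.1,0.2,4.69,3.50,0.09,0.176,0.005,0.002,4
0.5,0,0,0,1.31,1.83,0.00,0.120,0.004,0.000,4
0.5,0,0,0.2,2.63,1.97,0.00,0.125,0.007,0.000,4
0.5,0,0.1,0,2.38,1.90,0.00,0.125,0.008,0.000,4
0.5,0,0.1,0.2,2.69,2.32,0.00,0.176,0.009,0.000,4
0.5,0.5,0,0,2.81,2.60,0.00,0.209,0.007,0.000,4
0.5,0.5,0,0.2,3.25,2.74,0.00,0.296,0.005,0.000,4
0.5,0.5,0.1,0,3.19,2.70,0.00,0.164,0.006,0.000,4
0.5,0.5,0.1,0.2,3.50,2.90,0.00,0.183,0.008,0.000,4
0.5,1,0,0,3.81,3.19,0.05,0.164,0.006,0.002,4
0.5,1,0,0.2,4.00,3.38,0.07,0.204,0.007,0.003,4
0.5,1,0.1,0,4.13,3.27,0.10,0.125,0.005,0.003,4
0.5,1,0.1,0.2,4.44,3.39,0.12,0.157,0.006,0.002,4
0.5,2,0,0,4.56,3.64,0.15,0.223,0.005,0.002,4
0.5,2,0,0.2,5.13,3.72,0.16,0.155,0.006,0.002,4
0.5,2,0.1,0,5.31,3.66,0.18,0.198,0.006,0.002,4
0.5,2,0.1,0.2,5.50,3.81,0.20,0.129,0.007,0.003,4
1,0,0,0,2.75,2.61,0.00,0.144,0.006,0.000,4
1,0,0,0.2,3.19,2.81,0.00,0.164,0.006,0.000,4
1,0,0.1,0,3.31,2.76,0.00,0.151,0.006,0.000,4
1,0,0.1,0.2,3.56,3.03,0.00,0.223,0.013,0.000,4
1,0.5,0,0,4.19,3.23,0.08,0.188,0.005,0.003,4
1,0.5,0,0.2,4.38,3.41,0.08,0.180,0.006,0.003,4
1,0.5,0.1,0,4.44,3.44,0.10,0.157,0.004,0.003,4
1,0.5,0.1,0.2,4.56,3.53,0.13,0.182,0.005,0.003,4
1,1,0,0,4.50,3.55,0.11,0.224,0.005,0.003,4
1,1,0,0.2,4.75,3.65,0.13,0.112,0.004,0.002,4
1,1,0.1,0,4.81,3.61,0.14,0.136,0.007,0.003,4
1,1,0.1,0.2,5.19,3.68,0.15,0.136,0.006,0.003,4
1,2,0,0,5.81,3.76,0.21,0.136,0.005,0.002,4
1,2,0,0.2,6.00,3.90,0.22,0.158,0.006,0.003,4
1,2,0.1,0,6.19,3.80,0.24,0.164,0.006,0.003,4
1,2,0.1,0.2,6.50,3.99,0.25,0.129,0.006,0.003,4
2,0,0,0,4.44,3.36,0.06,0.157,0.004,0.004,4
2,0,0,0.2,4.63,3.47,0.07,0.125,0.004,0.003,4
2,0,0.1,0,4.75,3.39,0.08,0.112,0.006,0.004,4
2,0,0.1,0.2,4.94,3.58,0.10,0.143,0.006,0.003,4
2,0.5,0,0,4.69,3.66,0.18,0.120,0.005,0.003,4
2,0.5,0,0.2,4.88,3.80,0.19,0.180,0.007,0.003,4
2,0.5,0.1,0,5.25,3.72,0.21,0.144,0.004,0.003,4
2,0.5,0.1,0.2,5.50,3.90,0.24,0.129,0.007,0.004,4
2,1,0,0,6.06,3.86,0.22,0.170,0.004,0.003,4
2,1,0,0.2,5.88,3.89,0.23,0.180,0.008,0.003,4
2,1,0.1,0,5.75,3.78,0.25,0.194,0.007,0.003,4
2,1,0.1,0.2,5.00,3.91,0.26,0.183,0.006,0.003,4
2,2,0,0,4.00,3.90,0.25,0.183,0.005,0.002,4
2,2,0,0.2,4.31,3.89,0.25,0.120,0.005,0.003,4
2,2,0.1,0,4.56,3.82,0.27,0.157,0.006,0.002,4
2,2,0.1,0.2,3.00,3.71,0.30,0.183,0.006,0.004,4
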