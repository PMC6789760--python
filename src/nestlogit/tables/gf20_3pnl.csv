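item,alpha,beta,logit_gamma,lam1,lam2,lam3,lam4,zeta1,zeta2,zeta3,zeta4,se_alpha,se_beta,se_logit_gamma,se_lam1,se_lam2,se_lam3,se_lam4,se_zeta1,se_zeta2,se_zeta3,se_zeta4
1,1.443,2.843,-3.065,0.396,0.927,0.668,1.132,-0.323,2.768,1.196,1.623,0.125,0.231,4.501,0.474,0.304,0.342,0.343,0.761,0.5,0.552,0.532
2,1.319,2.564,-4.277,-1.109,-0.271,-0.132,-0.452,-3.22,-1.141,-1.522,-1.709,0.086,0.111,4.167,0.323,0.174,0.207,0.209,0.54,0.226,0.259,0.288
3,1.719,1.608,-2.921,-0.824,-0.424,-0.883,-0.496,-1.086,-1.13,-1.378,-0.549,0.149,0.131,1.645,0.164,0.176,0.177,0.146,0.194,0.193,0.216,0.158
4,0.625,1.181,-4.813,0.684,2.387,2.171,-0.076,2.602,6.763,3.888,-0.23,0.051,0.065,4.023,0.588,0.581,0.606,0.769,1.136,1.1,1.115,1.535
5,2.34,1.664,-3.412,0.536,0.127,0.3,-0.207,1.795,0.298,1.263,-0.421,0.168,0.098,1.215,0.191,0.227,0.197,0.252,0.242,0.293,0.252,0.343
6,1.363,1.418,-3.134,-1.265,-0.982,-1.262,-1.159,-2.399,-2.706,-2.295,-2.695,0.125,0.158,2.55,0.183,0.217,0.176,0.208,0.23,0.264,0.22,0.263
7,1.826,1.854,-6.09,-0.338,-0.431,-1.327,-1.119,-0.425,-0.565,-1.599,-1.751,0.09,0.081,4.208,0.155,0.16,0.197,0.213,0.165,0.174,0.259,0.278
8,1.378,1.394,-4.012,-0.752,-0.427,-0.002,-1.495,0.168,-0.543,0.512,-2.442,0.103,0.123,4.313,0.147,0.176,0.141,0.263,0.154,0.183,0.133,0.381
9,2.648,1.969,-2.061,0.408,0.533,0.422,0.297,1.305,0.828,0.176,1.664,0.2,0.116,0.37,0.225,0.249,0.285,0.212,0.298,0.32,0.364,0.286
10,1.461,-0.87,-1.983,0.317,0.456,0.25,1.137,0.701,0.356,-0.061,2.034,0.152,0.172,0.274,0.119,0.132,0.141,0.113,0.133,0.141,0.156,0.118
11,2.527,-3.084,-1.619,0.279,-0.374,0.581,-0.113,0.605,0.515,0.824,0.819,0.315,0.385,0.096,0.106,0.102,0.106,0.099,0.087,0.092,0.085,0.085
12,2.308,0.758,-2.504,-0.344,-1.748,-0.542,0.148,1.12,-1.412,0.573,0.99,0.159,0.093,0.359,0.18,0.243,0.191,0.188,0.162,0.296,0.178,0.161
13,1.593,-0.374,-7.481,-0.63,0.525,-0.116,0.852,0.615,1.446,1.596,2.837,0.075,0.055,3.982,0.194,0.191,0.181,0.177,0.216,0.189,0.189,0.177
14,2.249,-1.038,-3.833,-0.51,-0.646,-0.473,-0.183,-0.576,-1.635,-0.297,0.452,0.142,0.102,0.434,0.104,0.144,0.098,0.085,0.094,0.143,0.086,0.069
15,4.703,-6.146,-2.335,-0.596,-0.8,-0.59,-0.707,-0.344,0.144,-0.721,-0.422,0.663,0.831,0.089,0.088,0.079,0.097,0.089,0.067,0.061,0.075,0.07
16,4.626,-5.091,-1.638,-0.152,0.446,0.824,-0.214,1.089,0.205,0.404,-0.452,0.608,0.675,0.072,0.088,0.112,0.115,0.118,0.075,0.086,0.084,0.105
17,2.613,-3.013,-2.142,0.328,0.52,1.452,0.162,2.774,3.387,1.618,1.434,0.277,0.313,0.117,0.182,0.18,0.211,0.198,0.188,0.186,0.201,0.202
18,2.21,-1.798,-3.415,0.377,-0.242,0.321,0.122,1.444,0.342,1.618,2.407,0.159,0.143,0.3,0.144,0.16,0.141,0.133,0.129,0.156,0.127,0.122
19,3.167,-4.95,-1.672,-0.901,-0.241,-0.773,-0.3,-1.09,0.344,-0.911,0.434,0.523,0.76,0.076,0.104,0.076,0.1,0.074,0.101,0.061,0.092,0.06
20,2.233,-4.111,-1.827,-0.659,0.381,0.315,-0.628,-1.018,0.205,0.537,-0.551,0.357,0.552,0.089,0.102,0.079,0.073,0.089,0.1,0.064,0.06,0.084
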