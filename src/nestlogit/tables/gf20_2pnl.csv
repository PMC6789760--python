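item,alpha,beta,lam1,lam2,lam3,lam4,zeta1,zeta2,zeta3,zeta4,se_alpha,se_beta,se_lam1,se_lam2,se_lam3,se_lam4,se_zeta1,se_zeta2,se_zeta3,se_zeta4
1,1.549,2.954,0.426,1.067,0.744,1.327,-0.312,2.878,1.248,1.771,0.103,0.113,0.535,0.341,0.383,0.382,0.805,0.523,0.579,0.554
2,1.397,2.614,-1.189,-0.297,-0.123,-0.442,-3.219,-1.154,-1.509,-1.669,0.091,0.096,0.357,0.194,0.229,0.231,0.548,0.235,0.266,0.292
3,1.747,1.736,-0.915,-0.392,-0.914,-0.559,-1.147,-1.094,-1.369,-0.593,0.089,0.077,0.183,0.193,0.195,0.163,0.205,0.197,0.222,0.167
4,0.646,1.2,0.828,2.623,2.413,0.132,2.746,6.883,4.011,0.168,0.053,0.048,0.65,0.646,0.671,0.821,1.15,1.122,1.136,1.476
5,2.417,1.819,0.648,0.18,0.386,-0.077,1.893,0.351,1.343,-0.259,0.119,0.093,0.215,0.255,0.221,0.279,0.26,0.313,0.27,0.355
6,1.412,1.524,-1.426,-1.127,-1.334,-1.266,-2.516,-2.816,-2.308,-2.755,0.075,0.066,0.205,0.244,0.194,0.231,0.245,0.283,0.226,0.274
7,1.945,1.933,-0.373,-0.506,-1.447,-1.262,-0.445,-0.617,-1.647,-1.845,0.098,0.085,0.171,0.179,0.218,0.237,0.171,0.184,0.267,0.291
8,1.425,1.457,-0.868,-0.485,-0.01,-1.611,0.098,-0.573,0.507,-2.45,0.075,0.064,0.163,0.194,0.153,0.288,0.161,0.189,0.136,0.384
9,2.435,2.17,0.354,0.517,0.485,0.233,1.225,0.78,0.208,1.577,0.123,0.103,0.244,0.27,0.307,0.23,0.303,0.325,0.365,0.291
10,1.09,-0.336,0.327,0.472,0.248,1.177,0.701,0.359,-0.068,2.06,0.058,0.046,0.131,0.144,0.155,0.123,0.137,0.145,0.161,0.122
11,0.875,-0.991,0.318,-0.397,0.567,-0.116,0.613,0.501,0.834,0.817,0.055,0.048,0.109,0.107,0.107,0.103,0.088,0.093,0.085,0.086
12,2.087,0.992,-0.374,-1.895,-0.589,0.182,1.101,-1.492,0.542,1.008,0.098,0.069,0.195,0.264,0.206,0.202,0.168,0.306,0.185,0.167
13,1.626,-0.321,-0.718,0.558,-0.139,0.922,0.555,1.467,1.58,2.877,0.078,0.055,0.216,0.211,0.201,0.196,0.226,0.197,0.197,0.185
14,2.096,-0.804,-0.577,-0.696,-0.539,-0.221,-0.613,-1.659,-0.334,0.435,0.102,0.067,0.114,0.158,0.107,0.092,0.097,0.147,0.089,0.07
15,1.104,-1.803,-0.52,-0.781,-0.564,-0.68,-0.343,0.13,-0.73,-0.432,0.067,0.065,0.087,0.078,0.096,0.089,0.067,0.061,0.075,0.07
16,0.965,-1.06,-0.187,0.467,0.802,-0.199,1.074,0.209,0.407,-0.445,0.057,0.05,0.092,0.113,0.112,0.125,0.076,0.086,0.084,0.106
17,1.118,-1.309,0.31,0.512,1.364,0.149,2.761,3.379,1.632,1.423,0.064,0.056,0.196,0.193,0.217,0.212,0.189,0.187,0.201,0.204
18,1.781,-1.351,0.4,-0.291,0.321,0.097,1.451,0.316,1.619,2.397,0.09,0.069,0.156,0.175,0.152,0.144,0.131,0.159,0.129,0.124
19,0.675,-1.335,-0.936,-0.235,-0.812,-0.294,-1.112,0.342,-0.935,0.431,0.053,0.05,0.11,0.074,0.104,0.073,0.103,0.061,0.094,0.06
20,0.533,-1.463,-0.72,0.39,0.318,-0.68,-1.051,0.208,0.541,-0.578,0.053,0.05,0.11,0.079,0.074,0.095,0.103,0.064,0.06,0.087
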