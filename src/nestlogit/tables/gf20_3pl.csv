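item,alpha,beta,logit_gamma,se_alpha,se_beta,se_logit_gamma
1,1.417,2.855,-4.089,0.104,0.157,6.671
2,1.326,2.575,-5.002,0.087,0.104,6.298
3,1.735,1.633,-3.17,0.155,0.136,2.191
4,0.619,1.185,-5.598,0.051,0.057,6.083
5,2.462,1.719,-3.465,0.179,0.102,1.223
6,1.362,1.477,-4.939,0.083,0.089,6.479
7,1.891,1.884,-6.457,0.097,0.084,6.179
8,1.389,1.365,-3.355,0.141,0.178,3.531
9,2.593,2.061,-2.619,0.216,0.118,0.751
10,1.438,-0.852,-2.002,0.149,0.172,0.285
11,2.603,-3.188,-1.597,0.327,0.4,0.093
12,2.44,0.697,-2.171,0.177,0.099,0.276
13,1.577,-0.368,-7.978,0.076,0.055,6.064
14,2.191,-0.992,-4.072,0.146,0.106,0.616
15,4.52,-5.921,-2.352,0.608,0.762,0.09
16,5.056,-5.569,-1.622,0.754,0.841,0.071
17,2.815,-3.228,-2.099,0.311,0.353,0.111
18,2.104,-1.729,-3.465,0.156,0.143,0.343
19,3.085,-4.858,-1.673,0.52,0.759,0.077
20,2.248,-4.156,-1.817,0.372,0.58,0.089
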