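item,alpha,beta,se_alpha,se_beta
1,1.527,2.93,0.105,0.113
2,1.391,2.605,0.094,0.096
3,1.767,1.74,0.093,0.078
4,0.64,1.198,0.054,0.048
5,2.543,1.878,0.132,0.099
6,1.442,1.535,0.078,0.067
7,2.015,1.966,0.106,0.089
8,1.412,1.448,0.077,0.064
9,2.575,2.245,0.138,0.111
10,1.085,-0.335,0.059,0.046
11,0.878,-0.991,0.055,0.048
12,2.078,0.991,0.101,0.07
13,1.612,-0.316,0.079,0.054
14,2.121,-0.802,0.105,0.067
15,1.113,-1.807,0.068,0.066
16,0.981,-1.064,0.058,0.051
17,1.153,-1.321,0.065,0.057
18,1.736,-1.33,0.089,0.068
19,0.678,-1.335,0.054,0.05
20,0.532,-1.463,0.053,0.05
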