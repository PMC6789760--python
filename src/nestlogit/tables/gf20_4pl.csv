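item,alpha,beta,gamma,delta
1,1.821,3.391,0.002,0.988
2,1.999,2.898,0.266,0.979
3,2.558,1.988,0.161,0.969
4,1.697,2.979,0.002,0.844
5,3.222,2.097,0.08,0.982
6,2.028,1.88,0.125,0.952
7,2.667,2.501,0.045,0.969
8,2.415,1.622,0.24,0.951
9,3.54,2.45,0.148,0.987
10,1.683,-0.669,0.131,0.898
11,3.013,-3.462,0.176,0.934
12,3.235,0.976,0.133,0.969
13,1.988,0.021,0.001,0.876
14,5.037,-1.078,0.049,0.831
15,6.06,-7.593,0.09,0.934
16,11.675,-11.75,0.169,0.923
17,16.917,-14.883,0.132,0.787
18,2.079,-1.636,0.028,0.983
19,2.931,-4.739,0.158,0.998
20,2.369,-4.404,0.143,0.99
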