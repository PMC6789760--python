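item,beta,se_beta
1,2.783,0.072
2,2.569,0.068
3,1.513,0.055
4,1.454,0.055
5,1.291,0.053
6,1.475,0.055
7,1.588,0.056
8,1.404,0.054
9,1.542,0.055
10,-0.372,0.05
11,-1.137,0.052
12,0.762,0.051
13,-0.313,0.049
14,-0.662,0.05
15,-1.926,0.059
16,-1.186,0.053
17,-1.399,0.054
18,-1.192,0.053
19,-1.603,0.056
20,-1.808,0.058
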