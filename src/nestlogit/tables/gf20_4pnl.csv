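item,alpha,beta,gamma,delta,lam1,lam2,lam3,lam4,zeta1,zeta2,zeta3,zeta4
1,2.447,3.234,0.395,0.983,0.413,0.955,0.677,1.174,-0.314,2.778,1.189,1.64
2,1.733,2.875,0.149,0.983,-1.077,-0.283,-0.142,-0.448,-3.143,-1.15,-1.53,-1.697
3,2.364,1.832,0.168,0.975,-0.801,-0.428,-0.904,-0.482,-1.052,-1.132,-1.392,-0.534
4,1.517,2.702,0.016,0.852,0.69,2.391,2.175,0.049,2.619,6.79,3.913,0.015
5,2.474,1.897,0.001,0.99,0.5,0.121,0.258,-0.309,1.749,0.288,1.212,-0.542
6,2.063,1.698,0.192,0.956,-1.277,-1.048,-1.307,-1.155,-2.392,-2.766,-2.329,-2.673
7,2.323,2.377,0.002,0.972,-0.336,-0.421,-1.341,-1.087,-0.424,-0.556,-1.613,-1.706
8,2.26,1.575,0.225,0.955,-0.765,-0.426,0.005,-1.551,0.166,-0.539,0.515,-2.474
9,3.508,2.443,0.159,0.985,0.447,0.56,0.46,0.325,1.343,0.851,0.212,1.691
10,1.357,-0.757,0.104,0.999,0.332,0.473,0.278,1.152,0.711,0.368,-0.041,2.048
11,2.444,-3.023,0.165,1.0,0.286,-0.378,0.583,-0.11,0.608,0.512,0.829,0.82
12,2.766,0.948,0.098,0.976,-0.327,-1.817,-0.519,0.16,1.131,-1.481,0.59,0.997
13,1.576,-0.356,0.0,1.0,-0.64,0.555,-0.096,0.89,0.607,1.466,1.611,2.861
14,2.176,-0.98,0.019,1.0,-0.51,-0.661,-0.469,-0.177,-0.579,-1.646,-0.297,0.453
15,4.743,-6.281,0.088,1.0,-0.585,-0.799,-0.588,-0.704,-0.348,0.136,-0.727,-0.428
16,4.613,-5.115,0.162,1.0,-0.155,0.454,0.83,-0.225,1.087,0.21,0.413,-0.458
17,2.496,-2.914,0.104,1.0,0.357,0.555,1.501,0.196,2.792,3.409,1.641,1.454
18,2.146,-1.745,0.031,1.0,0.359,-0.264,0.303,0.102,1.437,0.332,1.611,2.398
19,3.048,-4.844,0.157,0.998,-0.912,-0.245,-0.784,-0.3,-1.096,0.343,-0.917,0.433
20,2.217,-4.113,0.139,0.991,-0.666,0.393,0.319,-0.633,-1.023,0.206,0.54,-0.555
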