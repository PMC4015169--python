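aa,ST1,ST2,ST3,ST4,ST5
A,-1.217,-0.892,0.237,-0.539,0.932
C,-0.892,-0.118,2.330,-0.468,-1.159
D,-0.477,0.716,-1.439,-1.119,-0.983
E,-0.052,1.160,-1.426,-0.803,-1.328
F,1.267,-1.064,0.082,-0.128,-0.376
G,-1.564,-0.941,0.248,-0.765,1.195
H,0.904,-0.170,0.370,-0.430,1.630
I,-0.146,-0.269,-0.350,2.473,-0.321
K,0.396,1.283,0.385,0.503,0.525
L,-0.040,0.042,0.244,0.288,-0.002
M,-0.042,0.770,2.355,0.163,-1.849
N,-0.335,0.778,-0.494,-0.611,0.471
P,-0.430,-1.411,0.175,-0.647,0.697
Q,0.100,1.223,-0.477,-0.280,0.116
R,0.925,2.177,0.567,0.549,1.936
S,-1.001,-0.106,-0.590,-0.921,0.087
T,-0.766,-0.369,-1.197,1.481,-0.490
V,-0.569,-0.713,-0.361,2.161,0.022
W,2.524,-1.426,0.105,-0.319,0.041
Y,1.413,-0.671,-0.766,-0.587,-1.146
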