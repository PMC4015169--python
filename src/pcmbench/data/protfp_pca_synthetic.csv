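aa,PC1,PC2,PC3,PC4,PC5,PC6,PC7,PC8
A,-1.313,-0.075,-0.603,-1.076,-0.370,0.485,0.331,1.197
C,-0.789,-0.032,-0.363,-0.341,-0.912,0.660,2.107,-1.011
D,-0.553,0.055,2.491,0.314,0.142,-0.006,0.137,0.605
E,-0.115,0.106,2.498,0.864,-0.384,-0.395,-0.692,0.830
F,0.843,-1.622,-0.349,-0.102,-0.818,1.446,-0.392,-0.198
G,-1.548,0.228,-0.446,-1.595,0.162,0.467,-0.732,-0.438
H,0.938,-0.458,0.043,-1.117,0.975,1.350,-2.401,0.854
I,-0.454,-0.547,-1.016,2.201,0.401,-0.174,-0.429,0.414
K,1.063,1.892,-1.022,-0.051,-0.437,-0.451,-1.431,-1.198
L,-0.269,-0.357,-0.576,0.555,-1.971,-0.249,0.156,1.478
M,-0.008,-0.135,-0.294,0.731,-2.101,-0.675,-0.959,-1.293
N,-0.121,0.825,0.796,-0.308,0.303,0.114,0.643,-1.049
P,-0.550,-0.443,-0.359,-1.586,0.674,-2.772,-0.049,0.664
Q,0.316,0.845,0.832,0.273,-0.254,-0.296,-0.082,-1.148
R,1.697,2.411,-0.682,0.146,0.334,0.147,1.247,1.898
S,-0.850,0.435,0.091,-0.818,0.024,0.516,0.342,-0.172
T,-0.735,0.129,-0.271,1.074,2.329,0.004,0.035,-1.313
V,-0.860,-0.533,-1.062,1.599,1.006,0.135,0.111,0.713
W,1.944,-1.842,-0.044,-0.464,0.425,-1.758,0.811,-0.414
Y,1.365,-0.882,0.337,-0.300,0.474,1.453,1.247,-0.418
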