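aa,BLOSUM1,BLOSUM2,BLOSUM3,BLOSUM4,BLOSUM5,BLOSUM6,BLOSUM7,BLOSUM8,BLOSUM9,BLOSUM10
A,0.010,0.269,-0.004,0.116,-0.056,0.212,-0.030,0.091,3.137,-0.529
C,-0.427,-0.331,-0.662,-0.318,-0.454,3.950,-0.403,-0.523,-0.036,-0.181
D,-0.982,-0.929,-0.970,-0.268,2.381,-0.085,-0.190,-0.803,-1.017,-0.472
E,-0.259,0.167,0.638,-0.043,2.315,-0.356,-0.372,-0.217,0.140,-0.968
F,0.373,0.771,-1.138,-0.905,-0.217,-0.582,-0.380,0.925,-0.286,-0.300
G,-1.859,-0.634,-0.923,-0.695,-1.224,-1.424,-1.157,-1.320,1.212,0.749
H,-0.709,-0.979,0.215,0.201,-0.354,0.158,-0.615,2.833,-0.408,0.028
I,1.607,-0.945,-0.965,-0.436,-0.236,-0.340,-0.276,-0.414,-0.338,-0.965
K,-0.147,0.003,2.137,-0.102,-0.269,-0.200,-0.132,-0.566,-0.076,-0.885
L,1.652,-0.287,-0.112,-0.287,-0.678,-0.057,-0.344,-0.546,-0.488,0.211
M,1.923,0.263,0.345,0.201,-0.045,0.003,-0.499,-0.322,-0.270,2.511
N,-0.902,-1.798,0.088,-0.736,-0.336,-0.428,0.963,0.247,-1.245,1.345
P,-0.481,-0.087,-0.571,3.982,-0.606,-0.258,-0.316,-0.312,-0.499,-0.178
Q,0.285,0.767,1.371,0.403,1.570,0.185,-0.514,0.055,0.141,1.205
R,-0.352,-0.347,2.482,-0.434,-1.322,-0.015,-0.265,-0.302,-0.376,-0.932
S,-0.346,0.051,-0.117,-0.039,0.576,0.195,1.349,0.317,1.457,1.590
T,0.014,0.367,-0.106,0.165,-0.349,-0.101,3.609,-0.170,-0.171,-0.562
V,1.523,-0.486,-0.692,-0.012,-0.020,-0.518,0.059,-0.426,0.407,-1.234
W,-0.980,3.064,-0.519,-0.559,-0.589,-0.099,-0.169,-0.836,-1.295,0.095
Y,0.058,1.102,-0.496,-0.236,-0.087,-0.239,-0.319,2.291,0.010,-0.527
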