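aa,T1,T2,T3,T4,T5,T6,T7,T8
A,-0.998,-0.889,0.287,-0.142,-1.373,-0.544,0.806,-1.040
C,-1.000,-0.363,2.302,-0.748,0.928,1.303,0.168,-0.822
D,-0.500,0.677,-1.351,-1.529,0.286,0.541,-0.204,-0.062
E,-0.191,1.117,-1.375,-1.417,0.806,-0.149,-0.419,0.718
F,1.362,-0.938,0.081,-0.268,0.368,-1.265,1.176,-0.128
G,-1.211,-0.904,0.340,-0.179,-1.596,-0.321,1.278,0.916
H,1.138,0.088,0.509,0.481,-1.356,1.715,0.963,1.576
I,-0.357,-0.440,-0.625,1.996,1.268,-0.486,-0.127,0.337
K,0.275,1.351,0.379,0.679,-0.043,-1.858,0.115,2.104
L,-0.166,0.006,0.186,0.121,-0.112,-2.149,-0.096,-1.437
M,-0.382,0.517,2.254,-0.522,1.967,-0.078,-0.262,0.737
N,-0.297,0.822,-0.395,-0.334,-0.660,0.644,0.019,-0.723
P,-0.188,-1.362,0.233,-0.291,-1.159,-0.269,-3.585,0.395
Q,0.012,1.262,-0.419,-0.222,-0.141,-0.046,-0.196,0.057
R,0.775,2.342,0.648,1.493,-1.093,0.590,-0.492,-1.754
S,-0.856,-0.114,-0.505,-0.854,-0.655,0.110,0.537,0.427
T,-0.833,-0.545,-1.370,1.058,0.948,1.549,0.033,0.246
V,-0.666,-0.880,-0.601,1.883,0.748,0.205,0.088,-0.442
W,2.674,-1.159,0.163,-0.148,0.079,0.651,-0.451,0.293
Y,1.408,-0.588,-0.741,-1.056,0.789,-0.143,0.650,-1.396
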