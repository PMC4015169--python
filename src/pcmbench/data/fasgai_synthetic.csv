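aa,F1,F2,F3,F4,F5,F6
A,-1.559,0.724,0.245,-0.640,-0.256,0.365
C,-0.556,0.843,0.042,-0.677,-0.510,0.633
D,0.008,-1.238,-2.197,-0.180,-0.479,0.100
E,0.852,-1.037,-2.203,-0.261,-0.736,-0.216
F,0.672,1.327,-0.219,-0.518,1.364,1.359
G,-2.184,0.161,0.335,-0.635,-0.176,0.311
H,-0.372,-0.684,0.380,-0.126,1.690,1.219
I,0.665,1.238,-0.027,2.055,-0.601,-0.116
K,0.849,-0.654,1.992,-0.455,-0.847,-0.333
L,0.732,1.675,-0.055,-0.834,-0.844,-0.188
M,1.136,1.404,-0.150,-0.933,-1.019,-0.564
N,-0.272,-1.087,-0.206,-0.231,-0.389,0.162
P,-1.380,-0.134,0.265,-0.344,0.709,-2.944
Q,0.604,-0.863,-0.260,-0.318,-0.652,-0.173
R,1.170,-1.642,2.179,0.002,-0.634,0.307
S,-1.120,-0.223,0.044,-0.464,-0.340,0.468
T,-0.754,-0.654,-0.015,2.492,-0.040,-0.021
V,-0.209,0.959,0.066,2.156,-0.325,0.118
W,1.122,0.187,-0.090,-0.058,2.416,-1.876
Y,0.595,-0.302,-0.126,-0.031,1.669,1.390
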