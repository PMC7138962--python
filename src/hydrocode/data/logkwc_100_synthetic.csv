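aa,value
A,1.39
C,1.05
D,-5.18
E,-3.99
F,2.18
G,0.84
H,-2.65
I,3.61
K,-3.20
L,3.61
M,1.72
N,-3.88
P,1.10
Q,-3.20
R,-9.04
S,-1.86
T,-1.34
V,2.96
W,1.71
Y,0.17
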