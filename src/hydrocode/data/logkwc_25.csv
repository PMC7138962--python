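aa,value
A,1.33
C,0.94
D,-6.39
E,-4.99
F,2.18
G,0.69
H,-3.42
I,3.61
K,-4.07
L,3.61
M,1.72
N,-4.87
P,1.00
Q,-4.06
R,-10.94
S,-2.49
T,-1.88
V,2.96
W,1.71
Y,-0.10
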