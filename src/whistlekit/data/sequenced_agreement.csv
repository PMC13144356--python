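category,n,splits,printed_agreement_pct
A,118,118,100
B,27,27,100
C,6,3/3,50
D,11,10/1,90
E,4,4,100
F,4,2/2,50
G,27,26/1,96
H,18,18,100
I,3,3,100
J,6,2/4,67
K,16,16,100
L,70,70,100
M,13,13,100
N,3,3,100
O,42,17/25,59
P,8,8,100
Q,8,7/1,88
R,4,3/1,75
S,8,4/4,50
T,19,18/1,95
U,67,37/29/1,55
V,4,4,100
W,11,9/2,82
Y,11,11,100
Z,407,186/50/171,46
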