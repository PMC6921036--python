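residue,heavy_atoms,hbond_donors,hbond_acceptors
A,1,0,0
R,7,5,1
N,4,2,2
D,4,0,4
C,2,1,0
Q,5,2,2
E,5,0,4
G,0,0,0
H,6,1,1
I,4,0,0
L,4,0,0
K,5,3,1
M,4,0,0
F,7,0,0
P,3,0,0
S,2,1,2
T,3,1,2
W,10,1,0
Y,8,1,2
V,3,0,0
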