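residue,z1,z2,z3
A,-3.4535,-0.8314,0.8710
R,5.9227,-0.7707,1.9428
N,0.4104,-4.0436,-0.5900
D,0.1502,-2.2592,-1.7815
C,-1.8132,0.7809,-0.0062
Q,2.5410,-2.5906,0.0520
E,1.4594,-1.6961,-1.7366
G,-3.2706,-1.7938,0.5308
H,1.4195,0.2462,0.6037
I,-1.3560,1.8903,0.6660
L,-1.5348,1.8836,0.7144
K,2.7685,0.6670,2.5607
M,-0.0676,2.3168,0.4266
F,-0.0247,2.9087,-1.2433
P,-3.3838,-0.4244,-0.0096
S,-1.6519,-1.4774,0.3484
T,-1.3364,-0.5600,0.3103
W,1.7531,3.3182,-1.7406
Y,2.0819,1.7453,-1.1132
V,-2.9262,0.7588,0.6271
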