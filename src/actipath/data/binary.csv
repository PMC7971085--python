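species_i,species_j,kij_slope,kij_t0,source
H3O+,water,0.0,0.25,ref35
Na+,water,-0.007981,2.37999,ref35
K+,water,-0.004012,1.3959,ref35
NH4+,water,0.0,0.064,ref35
Cl-,water,0.0,-0.25,ref35
H2PO4-,water,0.0,0.25,ref35
Mg+2,water,0.0,-0.25,ref35
HPO4-2,water,0.0,0.25,ref35
SO4-2,water,0.0,0.25,ref35
K+,Cl-,0.0,0.064,ref35
K+,H2PO4-,0.0,0.018,ref35
K+,HPO4-2,0.0,1.000,ref35
K+,SO4-2,0.0,1.000,ref35
Na+,Cl-,0.0,0.317,ref35
Na+,H2PO4-,0.0,-0.071,ref35
Na+,HPO4-2,0.0,-1.000,ref35
Na+,SO4-2,0.0,-1.000,ref35
NH4+,Cl-,0.0,-0.566,ref35
NH4+,H2PO4-,0.0,-1.000,ref35
NH4+,HPO4-2,0.0,-0.556,ref35
NH4+,SO4-2,0.0,-1.000,ref35
Mg+2,Cl-,0.0,0.817,ref35
Mg+2,SO4-2,0.0,-1.000,ref35
H3O+,Cl-,0.0,0.654,ref35
glucose,water,0.00024,-0.1192,ref30
ATP,water,0.0,-0.1719,ref17
ADP,water,0.0,-0.1368,ref17
G6P,water,0.0,-0.065,ref18
F6P,water,0.0,-0.065,ref18
FBP,water,0.0,-0.1011,ref31
DHAP,water,0.0,0.0,ref22
GAP,water,0.0020333,-0.7064,ref24
3PG,water,0.0020333,-0.7064,ref24
2PG,water,0.0020333,-0.7064,ref24
NAD+,water,0.0,-0.074,ref32
NADH,water,0.0,-0.056,ref23
BPG,water,0.0,0.0,ref23
PEP,water,-0.005083,1.3316,ref12
pyruvate,water,0.0,0.1601,ref33
Tris,water,0.0,-0.047,ref18
TrisH+,water,0.0,-0.061,ref12
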