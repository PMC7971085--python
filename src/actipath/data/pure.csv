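species_id,m_seg,sigma,u_over_kB,n_donor,n_acceptor,eps_AB_over_kB,kappa_AB,z,sigma_model,source
glucose,6.6260,2.9860,244.53,5,5,5000.0,0.1,0,const,ref30
ATP,50.1628,2.1398,164.92,7,7,862.4,0.0001,0,const,ref17
ADP,18.8255,2.3283,169.55,6,6,1285.5,0.0001,0,const,ref17
G6P,22.3290,2.2266,243.31,5,5,5000.0,0.1,0,const,ref18
F6P,35.5936,1.8100,198.49,5,5,5000.0,0.1,0,const,ref18
FBP,19.8735,2.2922,215.77,5,5,5000.0,0.1,-3,const,ref31
DHAP,1.3472,4.1611,289.43,2,2,3614.4,0.1,-1,const,ref22
GAP,3.1100,4.6600,322.02,5,5,501.2,0.0001,-2,const,ref24
3PG,3.1100,4.6600,322.02,5,5,501.2,0.0001,-2,const,ref24
2PG,3.1100,4.6600,322.02,5,5,501.2,0.0001,-2,const,ref24
NAD+,25.0875,2.2714,299.04,8,8,3557.3,0.001,0,const,ref32
NADH,27.3947,2.7559,380.52,8,8,3711.9,0.001,-2,const,ref23
BPG,2.9053,2.3452,216.84,5,5,501.2,0.0001,-4,const,ref23
PEP,12.0070,2.2000,407.27,2,2,5000.0,0.1,-2,const,ref12
pyruvate,18.7471,2.0812,141.02,2,2,0.0,0.04509,-1,const,ref33
water,1.2047,2.7927,353.94,1,1,2425.7,0.04509,0,water_exp,ref34
Tris,6.3730,2.7484,302.16,1,1,4786.9,0.02027,0,const,ref18
TrisH+,10.2047,2.4081,348.10,4,4,10970.9,1e-06,1,const,ref18
K+,1.0,3.3417,200.00,0,0,0.0,0.0,1,const,ref35
Na+,1.0,2.8232,230.00,0,0,0.0,0.0,1,const,ref35
H3O+,1.0,3.4654,500.00,0,0,0.0,0.0,1,const,ref35
NH4+,1.0,3.5740,230.00,0,0,0.0,0.0,1,const,ref35
Mg+2,1.0,3.1327,1500.00,0,0,0.0,0.0,2,const,ref35
Cl-,1.0,2.7560,170.00,0,0,0.0,0.0,-1,const,ref35
H2PO4-,1.0,3.6505,95.00,0,0,0.0,0.0,-1,const,ref35
HPO4-2,1.0,2.1621,146.02,0,0,0.0,0.0,-2,const,ref35
SO4-2,1.0,2.6491,80.00,0,0,0.0,0.0,-2,const,ref35
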