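reaction_id,dRg0,dRg0_uncertainty,dRh0,dRh0_uncertainty,h_explicit,provenance
HK,-17.8,0.5,-23.8,0.7,False,equilibrium study; apparent constants at pH 7
GPI,2.94,0.05,12.1,0.2,False,equilibrium study; apparent constants at pH 7
PFK,-9.3,0.3,-9.5,0.0,False,Hansen equilibrium ratio + ePC-SAFT K_gamma; calorimetric enthalpy
ALD,22.0,2.0,48.97,0.0,False,Veech equilibrium ratio + ePC-SAFT K_gamma
TPI,7.1,0.3,18.0,7.0,False,equilibrium study; apparent constants at pH 7
GAPDH,51.5,0.4,4.6,0.1,True,equilibrium study; H+ treated as explicit reaction participant
PGK,-17.8,0.2,-49.0,9.0,False,equilibrium study; apparent constants at pH 7
PGAM,-5.8,0.0,2.0,5.0,False,Clarke equilibrium ratio; K_gamma = 1 (isomers)
ENO,-2.8,0.2,27.0,10.0,False,equilibrium study; apparent constants at pH 7
PK,-28.0,1.0,-9.3,0.0,False,equilibrium study; apparent constants at pH 7
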