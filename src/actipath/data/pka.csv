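metabolite_id,pka_values,charge_most_protonated,provenance
ATP,6.47,-3,secondary phosphate ionization; Alberty-style thermodynamic pKa at I=0
ADP,6.33,-2,secondary phosphate ionization; Alberty-style thermodynamic pKa at I=0
F6P,6.27,-1,secondary phosphate ionization; Alberty-style thermodynamic pKa at I=0
G6P,6.42,-1,secondary phosphate ionization; Alberty-style thermodynamic pKa at I=0
FBP,6.05;6.65,-2,two secondary phosphate ionizations; literature range 5.9-6.7
DHAP,5.90,-1,secondary phosphate ionization
GAP,6.45,-1,secondary phosphate ionization
BPG,7.00,-3,acyl-phosphate/phosphate ionization; poorly characterized
3PG,6.21,-2,secondary phosphate ionization
2PG,7.00,-2,secondary phosphate ionization
PEP,6.35,-2,secondary phosphate ionization
pyruvate,2.50,0,carboxylic acid; fully deprotonated above pH 4
phosphate,7.20,-1,H2PO4-/HPO4-2; thermodynamic pKa2
Tris,8.07,1,TrisH+/Tris at 298.15 K
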