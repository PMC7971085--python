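# PFK equilibrium medium (Hansen et al.): 33 mmol/kg Tris+HCl,
# 6.94 mmol/kg MgCl2, 50 mmol/kg KCl, 6 mmol/kg (NH4)2SO4 at pH 8, 303.15 K.
# Dithiothreitol and the enzyme are excluded.  Tris is speciated
# Tris/TrisH+ at the stated pH with Cl- as declared counter ion.
label: hansen_pfk
T: 303.15
pH: 8.0
buffers:
  - type: tris_hcl
    total_molality: 0.033
salts:
  KCl: 0.050
  MgCl2: 0.00694
  (NH4)2SO4: 0.006
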