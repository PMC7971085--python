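# Aldolase equilibrium medium (Veech et al.): 10 mmol/kg sodium phosphate
# buffer speciated at pH 7 (Na+ closes charge) plus 230 mmol/kg KCl,
# 311.15 K (ionic strength adjusted to ~0.25 M in the source).
label: veech_aldolase
T: 311.15
pH: 7.0
buffers:
  - type: sodium_phosphate
    total_molality: 0.010
salts:
  KCl: 0.230
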