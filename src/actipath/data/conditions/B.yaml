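# Conditions B: cytosol-like scenario — substrate/product ratios as in
# conditions A, but the activity-coefficient medium additionally contains
# every other glycolytic metabolite at its maximum molality plus
# 1 mmol/kg MgCl2 and 100 mmol/kg KCl (values stated in the source study).
# Metabolite ranges are the same placeholder set as in A.yaml (see the
# provenance note there).  All molalities in mol/kg.
label: B
T: 298.15
pH: 7.0
pressure: 1.01325e5
mode: activity
medium_scope: pathway
counter_cation: K+
counter_anion: Cl-
salts:
  MgCl2: 1.0e-3
  KCl: 0.100
metabolite_ranges:
  glucose:   [1.0e-3, 5.0e-3]
  G6P:       [2.0e-4, 8.0e-4]
  F6P:       [5.0e-5, 2.0e-4]
  FBP:       [2.0e-5, 2.0e-4]
  DHAP:      [5.0e-5, 3.0e-4]
  GAP:       [1.0e-5, 1.0e-4]
  BPG:       [1.0e-6, 1.0e-5]
  3PG:       [5.0e-5, 2.0e-4]
  2PG:       [1.0e-5, 5.0e-5]
  PEP:       [1.0e-5, 1.0e-4]
  pyruvate:  [5.0e-5, 5.0e-4]
  ATP:       [2.0e-3, 8.0e-3]
  ADP:       [2.0e-4, 1.0e-3]
  NAD+:      [5.0e-4, 2.0e-3]
  NADH:      [5.0e-5, 5.0e-4]
  phosphate: [5.0e-4, 3.0e-3]
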