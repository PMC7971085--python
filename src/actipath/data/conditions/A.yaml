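# Conditions A: best-case per-reaction scenario — only the substrate and
# product metabolites of the evaluated reaction are present; no salts.
# Metabolite min/max molalities are PLACEHOLDER values (the typeset
# supplementary concentration table is not reproduced in the main text):
# chosen once from physiological cytosolic ranges reported for muscle/yeast
# glycolysis, constrained to the qualitative pattern stated in the source
# study (GAPDH infeasible at best case; the other nine reactions feasible).
# Edit this file to recalibrate against the supplementary table; no code
# change is required.  All molalities in mol/kg.
label: A
T: 298.15
pH: 7.0
pressure: 1.01325e5
mode: activity
medium_scope: participants
counter_cation: K+
counter_anion: Cl-
salts: {}
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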