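# The ten glycolytic reactions, numbered 1-10.
# Stoichiometry is species-level, referenced to the fully deprotonated
# metabolite forms; nu > 0 products, nu < 0 substrates.  "H+" stoichiometry
# follows from charge balance of the deprotonated species; whether a_H+
# enters the reaction quotient is controlled by the standard-data
# `h_explicit` flag (only GAPDH).  Water (enolase product) is omitted from
# quotients (a_water ~ 1) and therefore not listed.
# "phosphate" is the total orthophosphate pool, speciated H2PO4-/HPO4-2 at
# the working pH before any equation-of-state call.
pathway: glycolysis
reactions:
  - id: HK
    number: 1
    display_name: hexokinase
    stoichiometry: {glucose: -1, ATP: -1, G6P: 1, ADP: 1, "H+": 1}
  - id: GPI
    number: 2
    display_name: glucose 6-phosphate isomerase
    stoichiometry: {G6P: -1, F6P: 1}
  - id: PFK
    number: 3
    display_name: phosphofructokinase
    stoichiometry: {F6P: -1, ATP: -1, FBP: 1, ADP: 1, "H+": 1}
  - id: ALD
    number: 4
    display_name: fructose-bisphosphate aldolase
    stoichiometry: {FBP: -1, DHAP: 1, GAP: 1}
  - id: TPI
    number: 5
    display_name: triosephosphate isomerase
    stoichiometry: {DHAP: -1, GAP: 1}
  - id: GAPDH
    number: 6
    display_name: glyceraldehyde 3-phosphate dehydrogenase
    stoichiometry: {GAP: -1, NAD+: -1, phosphate: -1, BPG: 1, NADH: 1, "H+": 1}
  - id: PGK
    number: 7
    display_name: phosphoglycerate kinase
    stoichiometry: {BPG: -1, ADP: -1, 3PG: 1, ATP: 1}
  - id: PGAM
    number: 8
    display_name: phosphoglycerate mutase
    stoichiometry: {3PG: -1, 2PG: 1}
  - id: ENO
    number: 9
    display_name: enolase
    stoichiometry: {2PG: -1, PEP: 1}
  - id: PK
    number: 10
    display_name: pyruvate kinase
    stoichiometry: {PEP: -1, ADP: -1, "H+": -1, pyruvate: 1, ATP: 1}
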