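# Bundled parameter tables — column schema and units

## pure.csv — ePC-SAFT pure-component parameters
| column | unit | meaning |
|---|---|---|
| species_id | – | unique identifier |
| m_seg | – | segment number (>0) |
| sigma | Å | segment diameter (for `sigma_model=water_exp` the value is the constant term of the temperature correlation sigma(T) = 2.7927 + 10.11 exp(-0.01775 T) - 1.417 exp(-0.01146 T), T in K) |
| u_over_kB | K | dispersion-energy parameter u/kB |
| n_donor, n_acceptor | – | association site counts of the two site types (donor sites bond only to acceptor sites) |
| eps_AB_over_kB | K | association-energy parameter (0 = no self-association; species may still cross-associate) |
| kappa_AB | – | association-volume parameter in [0, 1]; meaningful only if n_donor+n_acceptor > 0 |
| z | – | integer valence used by the Debye–Hückel term (0 for species modeled as neutral) |

## binary.csv — binary dispersion corrections
kij(T) = kij_t0 + kij_slope * T (T in K, kij dimensionless). Pairs are unordered;
pairs not listed default to kij = 0. Dispersion between like-charged species is
switched off irrespective of kij.

## standard_data.csv — standard reaction data (reference 298.15 K, pH 7)
dRg0 and dRh0 in kJ/mol; dRh0 treated as temperature-independent over
298.15–310.15 K. `h_explicit=True` means a_H+ = 10^-pH enters the reaction
quotient explicitly (the standard value is *not* an apparent, H+-free constant).

## pka.csv — acid–base ladders (Table S1 stand-in; declared replacement point)
`pka_values`: ascending, ';'-separated pKa values at the reference temperature;
`charge_most_protonated`: integer charge of the fully protonated state.
Temperature dependence of pKa neglected over 298.15–311.15 K.
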