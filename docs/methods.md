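# Methods

## Model

The package evaluates Gibbs energies of biochemical reactions from
thermodynamic activities. The activity of solute *i* is
`a_i = (m_i/m0) γ*_m,i` with standard molality `m0 = 1 mol/kg`;
`γ*_m,i = γ*_i x_w` converts the rational asymmetric coefficient
`γ*_i = φ_i/φ_i^∞` (fugacity coefficient in the mixture over its value at
infinite dilution in pure water, same T and P) to the molality scale. The
asymmetric normalization makes `γ*_i → 1` in the ideally diluted aqueous
reference state, which is also the reference of the bundled standard data.

### Residual Helmholtz energy (ePC-SAFT)

`a_res = a_hc + a_disp + a_assoc + a_ion`, per molecule, as a function of
temperature, number density and mole fractions:

* **Hard chain**: Boublík–Mansoori hard-sphere mixture term plus chain
  connectivity. Temperature-dependent segment diameters
  `d_i = σ_i (1 − 0.12 exp(−3 u_i/k_B T))` for molecular species; bare ions
  (charged species without association sites) keep `d_i = σ_i` — the
  convention of the electrolyte revision these ion parameters come from.
  Water's σ carries its own exponential T-correlation.
* **Dispersion**: the universal-constant power series with
  Lorentz–Berthelot combining, `u_ij = √(u_i u_j)(1 − k_ij(T))`,
  `k_ij(T) = k_ij,T0 + k_ij,slope·T`. Dispersion between two *charged*
  species exists only where a binary `k_ij` was fitted (the tabulated
  cation–anion pairs); unparameterized charged–charged pairs, and all
  like-charged pairs, interact without dispersion. Rationale: the ion
  dispersion energies were regressed against ion–water and salt data; the
  tabulated ±1.000 entries mark "dispersion off" bounds, so extending a
  geometric mean to never-fitted ion pairs would invent interactions the
  parameterization never saw.
* **Association**: Wertheim first-order theory. The site notation "X + Y"
  is read as X donor plus Y acceptor sites of two types that bond only to
  each other (a generalized 2B scheme; every tabulated species has X = Y).
  Association strength
  `Δ^{A_iB_j} = σ_ij³ g_ij^hs κ^{A_iB_j} (exp(ε^{A_iB_j}/k_BT) − 1)`.
  Cross-association follows Wolbach–Sandler: arithmetic-mean energy,
  geometric-mean volume with a `(√(σ_iσ_j)/σ_ij)³` correction. The
  arithmetic energy mean is essential: pyruvate carries `ε = 0` with
  `κ > 0` (induced association — it cross-associates with water but not
  with itself); a geometric mean would erase that behaviour. The site
  fractions are solved by damped successive substitution (damping 0.5,
  tolerance 1e-12 on the increment, cap 500 iterations); non-convergence
  raises an error carrying the residual.
* **Ion term**: Debye–Hückel,
  `a_ion = −(κ λ_B/3) Σ_j x_j z_j² χ_j(κσ_j)` with the Bjerrum length and
  screening parameter computed from the static permittivity of *pure*
  water (Malmberg–Maryott polynomial, composition-independent) and the
  per-species diameter σ_j. For `κσ < 0.01` the shape factor χ is
  evaluated by series to avoid cancellation.

### Derivatives, pressure, density

Pressure and chemical potentials are exact derivatives of `a_res`,
obtained by complex-step differentiation (step 1e-100), which is accurate
to machine precision for these analytic expressions — including through
the association fixed point and the √ρ of the ion term. Central finite
differences provide the independent cross-check (agreement to 1e-6
relative is asserted in the tests, for pressure and for every ln φ_i).
This keeps the model exactly thermodynamically consistent: Gibbs–Duhem
holds to the finite-difference error of the test, and the ion
chemical potential automatically contains the screening-length
composition derivative.

Density roots at (T, P) are bracketed on a packing-fraction grid (dilute
end set by the ideal-gas packing fraction; dense end 0.72) and polished
with Brent's method to |ΔP|/P < 1e-8; the liquid hint selects the densest
sign change, the vapor hint the most dilute. Packing fractions ≥ 0.74 are
rejected. Pressure defaults to 1.01325e5 Pa everywhere (ambient-lab
assumption; configurable), temperatures are valid within 273–373 K.

Infinite dilution is realized at trace mole fraction 1e-10. For neutral
species the reference is insensitive to the trace level (±1 order of
magnitude moves ln φ^∞ by < 1e-6); for charged species the ion term scales
as √x, so the reference carries an O(1e-3) operational wobble — negligible
against the O(1) medium effects it normalizes, and bounded in the tests.

## Reaction thermodynamics

* `K_c → K_m` is the identity under the dilute-solution assumption
  ρ_solution = 1 kg/L (flagged in output metadata).
* `K_γ = Π (γ*_m,i)^ν_i` is evaluated with metabolites at trace
  concentration in the stated salt/buffer medium (the standard-state
  reference is the ideally diluted solution and the salt medium dominates
  K_γ at mmol/kg metabolite levels); passing the measured equilibrium
  molalities evaluates the finite-composition alternative instead. The
  difference is ~10–15 % for the bundled media.
* Temperature: `Δᴿg⁰(T)` is always computed as
  `K_a(298.15) → van 't Hoff → K_a(T) → −RT ln K_a`, never by linear
  interpolation of Δᴿg⁰; `Δᴿh⁰` is treated as constant over
  298.15–311.15 K.
* pH: apparent constants transform between pH values with binding
  polynomials over each participant's pKa ladder plus the explicit-proton
  factor `10^{ν_H(pH₂−pH₁)}`, ν_H > 0 meaning H⁺ produced (referenced to
  the fully deprotonated species). pKa values are treated as
  temperature-independent over the working window.
* H⁺ conventions: the bundled standard Gibbs energies are apparent pH-7
  constants, except GAPDH, whose tabulated value treats H⁺ as an explicit
  participant; for that reaction `a_H+ = 10^{−pH}` enters the quotient in
  both activity and concentration modes. Water is omitted from quotients
  (`a_w ≈ 1`; the enolase product).
* Phosphate (GAPDH substrate) is a total pool: speciated H₂PO₄⁻/HPO₄²⁻ at
  the working pH inside the EOS medium, total molality in Q_m, and an
  effective γ taken as the speciation-weighted geometric mean.
* Uncertainties on derived Δᴿg⁰ are first-order: relative errors of K_m
  and K_γ enter as RT·(δK/K); the enthalpy error enters as
  |1 − T₂/T₁|·δΔᴿh⁰.

## Feasibility pipeline

Conditions A evaluate each reaction with substrates at their maximum and
products at their minimum declared molality, with only those participants
in the activity-coefficient medium; a positive Δᴿg here rules the reaction
out over the whole declared range (the concentration-mode version of this
bound is verified by randomized sampling in the tests; in activity mode
the medium feeds back through Q_γ, so the bound is reported, not
asserted). Conditions B keep the same quotient but add every other pathway
metabolite at its maximum plus 1 mmol/kg MgCl₂ and 100 mmol/kg KCl to the
γ-medium. Charged metabolites are balanced by the declared counter ion
(K⁺ by default; Cl⁻ for Tris·HCl, Na⁺ for sodium phosphate in the bundled
media) — never by an invented species. Feasibility is strictly Δᴿg < 0;
Δᴿg = 0 is reported as "at equilibrium".

The bundled per-metabolite ranges in `data/conditions/A.yaml` / `B.yaml`
are placeholders: physiological cytosolic values from the glycolysis
literature, constrained to the qualitative scenario the bundled standard
data describe (GAPDH infeasible at best case; the other nine reactions
feasible). They are declared replacement points — refining them against a
measured concentration table requires editing YAML only. Quantities that
depend on them (the absolute conditions-B Δᴿg values) inherit their
uncertainty; the sign structure is robust across plausible ranges.

## Synthetic condition generator

`fixtures.synthesize_conditions(seed, n)` draws metabolite ranges
log-uniformly over 0.01–20 mmol/kg and salt loads over 0–300 mmol/kg KCl /
0–10 mmol/kg MgCl₂ — spanning the bundled scenarios — with seeded NumPy
randomness. It emulates the *structure* of real condition sets (ranges,
salts, temperatures, pH), not their biological correlations (no covariance
between metabolite pools, no enzyme or crowder effects); tests passing on
synthetic sets demonstrate pipeline correctness and invariant preservation,
not biological realism of any particular scenario.

## Known limitations

* The electrolyte term reproduces mean ionic activity coefficients of
  NaCl/KCl within ~7–15 % up to 1 mol/kg and pure-water density within
  0.01 %. The published activity-coefficient ratios for the PFK and
  aldolase media (0.19 and 5.8) are reproduced in sign and order of
  magnitude (0.136 and 3.3 at trace dilution; 3.7 at finite equilibrium
  compositions for aldolase) but not within their printed precision: these
  ratios are highly sensitive to electrolyte-term conventions that differ
  between implementations (ion-size damping, ion–metabolite dispersion
  defaults, derivative treatment of the screening length). The convention
  set used here was chosen on physical grounds and is documented above;
  no parameter was fitted to the target ratios.
* No Born/solvation term, no composition-dependent permittivity, no
  explicit Mg²⁺–nucleotide complexation (Mg²⁺ acts only through its
  activity-coefficient contributions), no vapor–liquid equilibrium or
  critical-point capability, no compartmentalization.
* pKa ladders are literature defaults at reference temperature; the pH
  8 → 7 transform of the PFK chain moves by < 1 kJ/mol under ±0.2 pKa
  shifts (asserted in the tests).
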