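"""Physical constants and solvent correlations (SI unless noted)."""

from __future__ import annotations

import numpy as np

KB = 1.380649e-23  # Boltzmann constant, J/K
NAV = 6.02214076e23  # Avogadro number, 1/mol
R_GAS = KB * NAV  # molar gas constant, J/(mol K)
E_CHARGE = 1.602176634e-19  # elementary charge, C
EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m
MW_WATER = 0.01801528  # molar mass of water, kg/mol
P_AMBIENT = 1.01325e5  # default pressure, Pa (ambient-lab assumption)
T_REF = 298.15  # reference temperature for standard data, K
M0 = 1.0  # standard molality, mol/kg

ANGSTROM = 1.0e-10  # m


def water_relative_permittivity(T: float) -> float:
    """Static relative permittivity of pure liquid water.

    Malmberg & Maryott (1956) polynomial in Celsius temperature, valid
    0-100 degC.  Used as the (composition-independent) solvent permittivity
    of the Debye-Hueckel contribution.
    """
    t = T - 273.15
    return 87.740 - 0.40008 * t + 9.398e-4 * t**2 - 1.410e-6 * t**3


def molality_to_mole_fractions(molalities: dict[str, float]) -> dict[str, float]:
    """Convert solute molalities (mol/kg water) to mole fractions incl. water."""
    n_w = 1.0 / MW_WATER
    total = n_w + sum(molalities.values())
    x = {sp: m / total for sp, m in molalities.items()}
    x["water"] = n_w / total
    return x


def mole_fraction_water(molalities: dict[str, float]) -> float:
    n_w = 1.0 / MW_WATER
    return n_w / (n_w + sum(molalities.values()))


def debye_kappa(T: float, rho_number_si: float, xz2: float) -> float:
    """Inverse Debye screening length (1/m).

    ``rho_number_si``: total molecular number density (1/m^3);
    ``xz2``: sum over species of x_i * z_i^2.
    """
    eps = EPS0 * water_relative_permittivity(T)
    return float(np.sqrt(E_CHARGE**2 * rho_number_si * xz2 / (eps * KB * T)))


def bjerrum_length(T: float) -> float:
    """Bjerrum length of water (m) with the same permittivity correlation."""
    eps = EPS0 * water_relative_permittivity(T)
    return E_CHARGE**2 / (4.0 * np.pi * eps * KB * T)
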