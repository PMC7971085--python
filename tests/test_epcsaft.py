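"""Equation-of-state core: limits, derivatives, density roots, gamma*."""

from __future__ import annotations

import numpy as np
import pytest

from actipath.constants import KB, NAV, MW_WATER, bjerrum_length, molality_to_mole_fractions
from actipath.epcsaft import EPCSAFT, ActivityModel, DensityError
from actipath.parameters import ParameterRegistry, PureComponentParams

from conftest import random_liquid_state

P_ATM = 1.01325e5


def hard_sphere_registry(sigma=3.0, u=1e-9, m_seg=1.0):
    p = PureComponentParams("hs", m_seg, sigma, u)
    return ParameterRegistry({"hs": p})


# ---------------------------------------------------------------- limits
def test_ideal_gas_limit_all_terms_vanish(registry):
    """rho -> 0: every residual Helmholtz contribution -> 0."""
    eos = EPCSAFT(registry, ["water", "glucose", "K+", "Cl-"])
    x = np.array([0.9, 0.05, 0.025, 0.025])
    # the ion term decays as sqrt(rho), so the limit needs a very dilute state
    bd = eos.helmholtz_breakdown(298.15, 1.0e-20, x)
    for term in (bd.a_hc, bd.a_disp, bd.a_assoc, bd.a_ion):
        assert abs(term) < 1.0e-9
    assert bd.a_res == bd.a_hc + bd.a_disp + bd.a_assoc + bd.a_ion


def test_ideal_gas_pressure():
    """Non-interacting single segment at vanishing density: P = rho kB T."""
    eos = EPCSAFT(hard_sphere_registry(sigma=0.1), ["hs"])
    rho = 1.0e-18  # molecules / A^3
    P = eos.pressure(300.0, rho, np.array([1.0]))
    assert P == pytest.approx(rho * 1.0e30 * KB * 300.0, rel=1.0e-10)


def test_carnahan_starling_closed_form():
    """Single species, m=1, no assoc/charge: a_hc = (4 eta - 3 eta^2)/(1-eta)^2."""
    eos = EPCSAFT(hard_sphere_registry(), ["hs"])
    eta = 0.40
    tc = eos._tcache(300.0)
    rho = 6.0 * eta / (np.pi * tc["d"][0] ** 3)
    bd = eos.helmholtz_breakdown(300.0, rho, np.array([1.0]))
    expected = (4 * eta - 3 * eta**2) / (1 - eta) ** 2
    assert bd.a_hc == pytest.approx(expected, rel=1.0e-10)
    assert bd.a_assoc == 0.0
    assert bd.a_ion == 0.0


def test_ion_term_zero_without_charges(registry):
    eos = EPCSAFT(registry, ["water", "glucose"])
    bd = eos.helmholtz_breakdown(298.15, 0.03, np.array([0.95, 0.05]))
    assert bd.a_ion == 0.0


def test_ion_term_negative_for_salt(registry):
    """Debye-Hueckel is attractive for any electroneutral salt solution."""
    eos = EPCSAFT(registry, ["water", "Na+", "Cl-"])
    bd = eos.helmholtz_breakdown(298.15, 0.033, np.array([0.96, 0.02, 0.02]))
    assert bd.a_ion < 0.0


# ------------------------------------------------------------ association
def test_site_fractions_bounded_and_converged(registry, hansen_medium):
    x = hansen_medium.mole_fractions()
    eos = EPCSAFT(registry, list(x))
    xa = np.array([x[s] for s in x])
    st = eos.solve_density(hansen_medium.T, P_ATM, xa / xa.sum(), "liquid")
    names, Xd, Xa = eos.site_fractions(st.T, st.rho, st.x)
    assert len(names) > 0
    for X in (Xd, Xa):
        assert np.all(X > 0.0) and np.all(X <= 1.0)
    resid = eos.site_fraction_residual(st.T, st.rho, st.x)
    assert resid < 1.0e-10


def test_zero_kappa_means_zero_association():
    reg = ParameterRegistry(
        {
            "w": PureComponentParams(
                "w", 1.2047, 2.797, 353.94, 1, 1, 2425.7, 0.0
            )
        }
    )
    eos = EPCSAFT(reg, ["w"])
    bd = eos.helmholtz_breakdown(298.15, 0.033, np.array([1.0]))
    assert bd.a_assoc == 0.0


# ---------------------------------------------------------- pressure/density
def test_pure_water_liquid_density(registry):
    """Bundled water parameters reproduce the experimental liquid density."""
    eos = EPCSAFT(registry, ["water"])
    st = eos.solve_density(298.15, P_ATM, np.array([1.0]), "liquid")
    dens = st.rho * 1.0e30 / NAV * MW_WATER
    assert dens == pytest.approx(997.05, abs=5.0)
    eta = eos.packing_fraction(298.15, st.rho, st.x)
    assert 0.2 < eta < 0.6
    assert abs(eos.pressure(298.15, st.rho, st.x) - P_ATM) / P_ATM < 1.0e-8


def test_vapor_root_is_near_ideal():
    eos = EPCSAFT(hard_sphere_registry(sigma=0.1), ["hs"])
    T, P = 300.0, 1.0e-2
    st = eos.solve_density(T, P, np.array([1.0]), "vapor")
    rho_ideal = P / (KB * T) / 1.0e30
    assert st.rho == pytest.approx(rho_ideal, rel=1.0e-8)


def test_liquid_branch_positive_compressibility(registry):
    """+1% pressure from a converged liquid root raises the density."""
    eos = EPCSAFT(registry, ["water"])
    st1 = eos.solve_density(298.15, P_ATM, np.array([1.0]), "liquid")
    st2 = eos.solve_density(298.15, 1.01 * P_ATM, np.array([1.0]), "liquid")
    assert st2.rho > st1.rho


def test_density_solver_reports_failure():
    eos = EPCSAFT(hard_sphere_registry(), ["hs"])
    with pytest.raises(DensityError, match="no density root"):
        # a hard-sphere fluid has no liquid-like root at ambient pressure
        eos.solve_density(300.0, -1.0e9, np.array([1.0]), "liquid")


def test_non_electroneutral_composition_rejected(registry):
    eos = EPCSAFT(registry, ["water", "Na+"])
    with pytest.raises(ValueError, match="electroneutral"):
        eos.solve_density(298.15, P_ATM, np.array([0.99, 0.01]), "liquid")


# ------------------------------------------------- derivative cross-checks
@pytest.mark.parametrize("seed", range(5))
def test_pressure_analytic_vs_finite_difference(registry, seed):
    rng = np.random.default_rng(1000 + seed)
    eos = EPCSAFT(registry, ["water", "glucose", "Tris"])
    T, rho, x = random_liquid_state(eos, rng)
    assert eos.pressure(T, rho, x) == pytest.approx(
        eos.pressure_fd(T, rho, x), rel=1.0e-6
    )


def test_fugacity_derivatives_50_seeded_states(registry):
    """Complex-step vs central-difference ln phi at 50 randomized states."""
    rng = np.random.default_rng(42)
    neutral = EPCSAFT(registry, ["water", "glucose", "Tris", "ATP"])
    salty = EPCSAFT(registry, ["water", "Na+", "Cl-"])
    checked = 0
    while checked < 50:
        if checked % 2 == 0:
            eos = neutral
            T, rho, x = random_liquid_state(eos, rng)
        else:
            eos = salty
            T = rng.uniform(280.0, 340.0)
            m = rng.uniform(0.01, 1.0)
            xd = molality_to_mole_fractions({"Na+": m, "Cl-": m})
            x = np.array([xd[s] for s in ("water", "Na+", "Cl-")])
            eta = rng.uniform(0.3, 0.5)
            tc = eos._tcache(T)
            rho = 6.0 * eta / (np.pi * float(np.sum(x * eos.m * tc["d"] ** 3)))
        if eos.compressibility(T, rho, x) <= 0.05:
            continue  # mechanically unstable state; ln phi undefined
        a = eos.ln_phi(T, rho, x)
        b = eos.ln_phi_fd(T, rho, x)
        assert np.max(np.abs(a - b)) < 1.0e-6
        checked += 1


def test_ideal_mixture_has_zero_ln_phi():
    reg = ParameterRegistry(
        {
            "g1": PureComponentParams("g1", 1.0, 0.1, 1e-9),
            "g2": PureComponentParams("g2", 1.0, 0.1, 1e-9),
        }
    )
    eos = EPCSAFT(reg, ["g1", "g2"])
    lnphi = eos.ln_phi(300.0, 1.0e-15, np.array([0.4, 0.6]))
    assert np.max(np.abs(lnphi)) < 1.0e-8


@pytest.mark.parametrize(
    "species,mol",
    [
        (("water", "glucose", "Tris"), {"glucose": 0.4, "Tris": 0.2}),
        (("water", "K+", "Cl-"), {"K+": 0.3, "Cl-": 0.3}),
    ],
)
def test_gibbs_duhem_at_fixed_T_P(registry, species, mol):
    """Sum x_i d ln phi_i = 0 along a composition path at fixed T, P."""
    eos = EPCSAFT(registry, list(species))
    T = 298.15
    h = 1.0e-4

    def lnphi_at(scale):
        m = {k: v * scale for k, v in mol.items()}
        xd = molality_to_mole_fractions(m)
        x = np.array([xd[s] for s in species])
        st = eos.solve_density(T, P_ATM, x, "liquid")
        x0 = np.array([xd[s] for s in species])
        return x0, eos.ln_phi(T, st.rho, x0)

    x0, _ = lnphi_at(1.0)
    _, lp = lnphi_at(1.0 + h)
    _, lm = lnphi_at(1.0 - h)
    dlnphi = (lp - lm) / (2 * h)
    resid = abs(float(np.sum(x0 * dlnphi))) / max(1.0, float(np.max(np.abs(dlnphi))))
    assert resid < 1.0e-6


# ------------------------------------------------------- activity coefficients
def test_gamma_star_unity_at_reference(registry, model):
    """Trace metabolite in pure water is the reference state itself."""
    x = molality_to_mole_fractions({"glucose": 5.0e-9})
    g = model.gamma_star(298.15, P_ATM, x, species=["glucose"], molality_scale=False)
    assert g["glucose"] == pytest.approx(1.0, abs=1.0e-6)


def test_gamma_star_requires_water(registry, model):
    with pytest.raises(ValueError, match="water"):
        model.gamma_star(298.15, P_ATM, {"glucose": 1.0}, species=["glucose"])


def test_gamma_star_infinite_dilution_all_species(registry, model):
    """gamma* -> 1 as solute content -> 0 for every tabulated species."""
    for sp in registry.species_ids():
        if sp == "water":
            continue
        x = molality_to_mole_fractions({sp: 1.0e-8})  # x ~ 2e-10
        g = model.gamma_star(
            298.15, P_ATM, x, species=[sp], molality_scale=False
        )[sp]
        # charged species approach the limit as sqrt(x) via the ion term
        tol = 1.0e-5 if registry.get(sp).z == 0 else 5.0e-3
        assert g == pytest.approx(1.0, abs=tol), sp


def test_trace_reference_insensitivity_neutral(registry, model):
    """Neutral species: reference insensitive to the trace level (1e-6 rel)."""
    m1 = ActivityModel(registry)
    m2 = ActivityModel(registry)
    a = m1.ln_phi_infinite_dilution("glucose", 298.15, P_ATM, trace_x=1.0e-10)
    b = m2.ln_phi_infinite_dilution("glucose", 298.15, P_ATM, trace_x=1.0e-11)
    c = m2.ln_phi_infinite_dilution("glucose", 298.15, P_ATM, trace_x=1.0e-9)
    assert b == pytest.approx(a, abs=1.0e-6)
    assert c == pytest.approx(a, abs=1.0e-6)


def test_trace_reference_wobble_charged_bounded(registry):
    """Charged species: sqrt(x) ion-term scaling keeps the wobble < 5e-3."""
    m = ActivityModel(registry)
    a = m.ln_phi_infinite_dilution("FBP", 298.15, P_ATM, trace_x=1.0e-10)
    b = m.ln_phi_infinite_dilution("FBP", 298.15, P_ATM, trace_x=1.0e-11)
    assert abs(a - b) < 5.0e-3


def test_debye_hueckel_limiting_law(registry):
    """ln gamma*_ion -> -z^2 lambda_B kappa / 2 at vanishing ionic strength."""
    T = 298.15
    model = ActivityModel(registry)
    m_salt = 1.0e-4
    xd = molality_to_mole_fractions({"K+": m_salt, "Cl-": m_salt})
    g = model.gamma_star(
        T, P_ATM, xd, species=["K+", "Cl-"], molality_scale=False, trace_x=1.0e-12
    )
    # oracle: closed-form limiting law with the same permittivity correlation
    eos = EPCSAFT(registry, ["water", "K+", "Cl-"])
    x = np.array([xd[s] for s in ("water", "K+", "Cl-")])
    st = eos.solve_density(T, P_ATM, x, "liquid")
    rho_si = st.rho * 1.0e30
    lam = bjerrum_length(T)
    kappa = np.sqrt(4.0 * np.pi * lam * rho_si * float(np.sum(x * eos.z**2)))
    expected = -lam * kappa / 2.0  # z = +/-1
    mean_ln = 0.5 * (np.log(g["K+"]) + np.log(g["Cl-"]))
    assert mean_ln == pytest.approx(expected, rel=0.05)


def test_neutral_gamma_monotone_in_added_salt(registry, model):
    """gamma* of a neutral metabolite responds monotonically to KCl 0-0.3."""
    vals = []
    for m_kcl in [0.0, 0.05, 0.1, 0.2, 0.3]:
        mol = {"glucose": 5.0e-9}
        if m_kcl:
            mol.update({"K+": m_kcl, "Cl-": m_kcl})
        x = molality_to_mole_fractions(mol)
        vals.append(
            model.gamma_star(298.15, P_ATM, x, species=["glucose"])["glucose"]
        )
    diffs = np.diff(vals)
    assert np.all(diffs > 0) or np.all(diffs < 0)


def test_salt_activity_coefficient_reasonable(registry, model):
    """NaCl 1 mol/kg mean ionic activity coefficient near experiment (0.657)."""
    x = molality_to_mole_fractions({"Na+": 1.0, "Cl-": 1.0})
    g = model.gamma_star(298.15, P_ATM, x, species=["Na+", "Cl-"])
    miac = float(np.sqrt(g["Na+"] * g["Cl-"]))
    assert miac == pytest.approx(0.657, rel=0.15)


def test_residual_helmholtz_breakdown_sums(registry, hansen_medium):
    from actipath.epcsaft import residual_helmholtz

    x = hansen_medium.mole_fractions()
    eos = EPCSAFT(registry, list(x))
    xa = np.array([x[s] for s in x])
    st = eos.solve_density(hansen_medium.T, P_ATM, xa / xa.sum(), "liquid")
    bd = residual_helmholtz(st, registry)
    assert bd.a_res == bd.a_hc + bd.a_disp + bd.a_assoc + bd.a_ion
    assert np.isfinite([bd.a_hc, bd.a_disp, bd.a_assoc, bd.a_ion]).all()
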