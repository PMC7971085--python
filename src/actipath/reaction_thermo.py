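"""Equilibrium-constant algebra and Gibbs energies of reaction.

The thermodynamic equilibrium constant Ka = Km * Kgamma combines the
molality-based equilibrium ratio Km (standard molality m0 = 1 mol/kg) with
the activity-coefficient ratio Kgamma predicted by the equation of state.
Standard Gibbs energies follow from dg0 = -RT ln Ka; the van 't Hoff
relation with a temperature-independent standard reaction enthalpy moves Ka
between temperatures, and binding polynomials move apparent constants
between pH values.

Reaction quotients under non-equilibrium conditions use activities
a_i = (m_i/m0) gamma*_m,i; for reactions whose standard data treat H+ as an
explicit participant, a_H+ = 10^-pH enters the quotient directly.  Water is
omitted from quotients (a_water ~ 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .constants import M0, P_AMBIENT, R_GAS, T_REF
from .epcsaft import ActivityModel
from .media import TRACE_MOLALITY, Medium, close_charge
from .parameters import ParameterRegistry, StandardData, default_registry
from .speciation import AcidBaseLadder, acid_fraction, load_pka_table, transform_K_pH

H_PLUS = "H+"
WATER = "water"
PHOSPHATE = "phosphate"  # total orthophosphate pool, speciated before EOS calls

R_KJ = R_GAS / 1000.0  # kJ/(mol K)


@dataclass(frozen=True)
class ReactionSpec:
    """Signed stoichiometry of one biochemical reaction (products > 0)."""

    reaction_id: str
    stoichiometry: dict
    display_name: str = ""
    number: int | None = None

    def __post_init__(self) -> None:
        nus = [v for s, v in self.stoichiometry.items() if s != H_PLUS]
        if not any(v < 0 for v in nus) or not any(v > 0 for v in nus):
            raise ValueError(
                f"{self.reaction_id}: need at least one substrate and one product"
            )

    @property
    def participants(self) -> list[str]:
        """Species entering the quotient (no H+, no water)."""
        return [s for s in self.stoichiometry if s not in (H_PLUS, WATER)]

    @property
    def nu_h(self) -> float:
        return float(self.stoichiometry.get(H_PLUS, 0.0))

    def substrates(self) -> list[str]:
        return [s for s in self.participants if self.stoichiometry[s] < 0]

    def products(self) -> list[str]:
        return [s for s in self.participants if self.stoichiometry[s] > 0]


@dataclass(frozen=True)
class EquilibriumRecord:
    """A measured equilibrium-concentration ratio with its medium."""

    reaction_id: str
    K_value: float
    basis: str  # "molarity" | "molality"
    T: float
    pH: float
    medium: Medium | None = None
    metabolite_molalities: dict | None = None  # equilibrium levels if known
    K_uncertainty: float = 0.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.K_value <= 0:
            raise ValueError("K_value must be positive")


# ---------------------------------------------------------------------------
def km_from_kc(record: EquilibriumRecord) -> tuple[float, dict]:
    """Molarity- to molality-based K under the rho_solution = 1 kg/L assumption.

    Dilute aqueous media: concentration in mmol/L equals molality in
    mmol/kg, so the mapping is the identity; the returned metadata flags the
    assumption whenever a conversion actually happened.
    """
    if record.basis == "molality":
        return record.K_value, {"converted": False}
    return record.K_value, {
        "converted": True,
        "assumption": "solution density 1 kg/L (c_i = m_i)",
    }


def vant_hoff(K_at_T1: float, dRh0_kJ: float, T1: float, T2: float) -> float:
    """Integrated van 't Hoff step with temperature-independent dRh0."""
    for T in (T1, T2):
        if not 273.0 <= T <= 373.0:
            raise ValueError(f"temperature {T} K outside [273, 373] K")
    return K_at_T1 * math.exp(-(dRh0_kJ / R_KJ) * (1.0 / T2 - 1.0 / T1))


def dg0_from_ka(Ka: float, T: float) -> float:
    """Standard Gibbs energy of reaction, kJ/mol."""
    if Ka <= 0:
        raise ValueError("Ka must be positive")
    return -R_KJ * T * math.log(Ka)


def ka_from_dg0(dg0_kJ: float, T: float) -> float:
    return math.exp(-dg0_kJ / (R_KJ * T))


def dg0_at_T(std: StandardData, T: float) -> float:
    """dg0(T) via Ka(298.15) -> van 't Hoff -> Ka(T) -> dg0, kJ/mol."""
    ka_ref = ka_from_dg0(std.dRg0, T_REF)
    return dg0_from_ka(vant_hoff(ka_ref, std.dRh0, T_REF, T), T)


# ---------------------------------------------------------------------------
def _gamma_for_participants(
    reaction: ReactionSpec,
    medium: Medium,
    model: ActivityModel,
    registry: ParameterRegistry,
    metabolite_molalities: dict | None,
    molality_scale: bool,
    ladders: dict[str, AcidBaseLadder] | None = None,
    counter_cation: str = "K+",
    counter_anion: str = "Cl-",
) -> dict:
    """gamma* of every quotient participant in the (possibly extended) medium.

    Participants absent from the medium are added at trace molality; the
    GAPDH phosphate pool is speciated H2PO4-/HPO4-2 at the medium pH and its
    effective gamma is the speciation-weighted geometric mean.  Finite
    charged additions are balanced by the declared counter ion.
    """
    ladders = ladders or load_pka_table()
    f_h2 = acid_fraction(ladders[PHOSPHATE], medium.pH)
    extra: dict[str, float] = {}
    levels = dict(metabolite_molalities or {})
    for sp in reaction.participants:
        m = levels.get(sp, TRACE_MOLALITY)
        if sp == PHOSPHATE:
            extra["H2PO4-"] = extra.get("H2PO4-", 0.0) + m * f_h2
            extra["HPO4-2"] = extra.get("HPO4-2", 0.0) + m * (1.0 - f_h2)
        else:
            extra[sp] = extra.get(sp, 0.0) + m
    mol = dict(medium.molalities)
    for sp, m in extra.items():
        mol[sp] = mol.get(sp, 0.0) + m
    mol = close_charge(mol, registry, counter_cation, counter_anion)
    x = Medium(medium.label, medium.T, medium.pH, mol, medium.P).mole_fractions()
    species = sorted({s for s in extra})
    gammas = model.gamma_star(
        medium.T, medium.P, x, species=species, molality_scale=molality_scale
    )
    out = {}
    for sp in reaction.participants:
        if sp == PHOSPHATE:
            out[sp] = float(
                math.exp(
                    f_h2 * math.log(gammas["H2PO4-"])
                    + (1.0 - f_h2) * math.log(gammas["HPO4-2"])
                )
            )
        else:
            out[sp] = gammas[sp]
    return out


def k_gamma(
    reaction: ReactionSpec,
    medium: Medium,
    registry: ParameterRegistry | None = None,
    model: ActivityModel | None = None,
    metabolite_molalities: dict | None = None,
    molality_scale: bool = True,
) -> float:
    """Activity-coefficient ratio Kgamma = prod_i (gamma*_m,i)^nu_i.

    Metabolites default to trace concentration (ideally diluted standard
    state); pass ``metabolite_molalities`` to evaluate at the finite
    equilibrium composition instead.  H+ and water are excluded.
    """
    registry = registry or default_registry()
    model = model or ActivityModel(registry)
    gammas = _gamma_for_participants(
        reaction, medium, model, registry, metabolite_molalities, molality_scale
    )
    lnk = sum(
        reaction.stoichiometry[sp] * math.log(gammas[sp])
        for sp in reaction.participants
    )
    return float(math.exp(lnk))


def reaction_quotient(
    reaction: ReactionSpec,
    metabolite_molalities: dict,
    medium: Medium,
    registry: ParameterRegistry | None = None,
    model: ActivityModel | None = None,
    mode: str = "activity",
    h_explicit: bool = False,
    gamma_medium_molalities: dict | None = None,
) -> dict:
    """Reaction quotient Q under non-equilibrium conditions.

    mode="activity": Qa = Qm * Qgamma (* a_H+^nu_H if ``h_explicit``);
    mode="concentration": Qm only (classical approach, but a_H+ still
    enters for ``h_explicit`` reactions since pH is a measured condition).

    ``gamma_medium_molalities`` optionally supplies the molalities used for
    the activity-coefficient medium when they differ from the quotient
    molalities (conditions-B scenario: non-participants at maximum).
    Returns a dict with Qm, Qgamma, Q and lnQ.
    """
    registry = registry or default_registry()
    for sp in reaction.participants:
        if metabolite_molalities.get(sp, 0.0) <= 0.0:
            raise ValueError(f"non-positive molality for participant {sp!r}")
    ln_qm = sum(
        reaction.stoichiometry[sp] * math.log(metabolite_molalities[sp] / M0)
        for sp in reaction.participants
    )
    if h_explicit:
        ln_qm += reaction.nu_h * math.log(10.0 ** (-medium.pH))
    q_gamma = 1.0
    if mode == "activity":
        model = model or ActivityModel(registry)
        levels = dict(gamma_medium_molalities or {})
        for sp in reaction.participants:
            levels.setdefault(sp, metabolite_molalities[sp])
        q_gamma = k_gamma(
            reaction, medium, registry, model, metabolite_molalities=levels
        )
    elif mode != "concentration":
        raise ValueError(f"unknown mode {mode!r}")
    ln_q = ln_qm + math.log(q_gamma)
    return {
        "Qm": math.exp(ln_qm),
        "Qgamma": q_gamma,
        "Q": math.exp(ln_q),
        "lnQ": ln_q,
    }


def gibbs_of_reaction(dg0_kJ: float, Q: float, T: float) -> float:
    """dg = dg0 + RT ln Q, kJ/mol; negative means spontaneous as written."""
    return dg0_kJ + R_KJ * T * math.log(Q)


# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class StandardGibbsResult:
    reaction_id: str
    dg0: float  # kJ/mol at target T, pH
    uncertainty: float
    T: float
    pH: float
    details: dict = field(default_factory=dict)


def derive_standard_gibbs(
    record: EquilibriumRecord,
    reaction: ReactionSpec,
    dRh0_kJ: float,
    registry: ParameterRegistry | None = None,
    ladders: dict[str, AcidBaseLadder] | None = None,
    model: ActivityModel | None = None,
    target_T: float = T_REF,
    target_pH: float = 7.0,
    k_gamma_value: float | None = None,
    k_gamma_rel_uncertainty: float = 0.0,
    dRh0_uncertainty: float = 0.0,
) -> StandardGibbsResult:
    """Full standard-data chain: Km -> Ka = Km Kgamma -> pH -> T -> dg0.

    Kgamma is predicted with the EOS in the record's medium (metabolites at
    trace unless the record carries equilibrium molalities) or may be
    supplied directly via ``k_gamma_value`` (e.g. the isomer assumption
    Kgamma = 1).  First-order uncertainty propagation combines the relative
    error of Km, the supplied relative error of Kgamma, and the enthalpy
    error over the temperature hop.
    """
    registry = registry or default_registry()
    ladders = ladders or load_pka_table()
    km, meta = km_from_kc(record)
    if k_gamma_value is None:
        if record.medium is None:
            raise ValueError("record has no medium; pass k_gamma_value")
        k_gamma_value = k_gamma(
            reaction,
            record.medium,
            registry,
            model,
            metabolite_molalities=record.metabolite_molalities,
        )
    ka_meas = km * k_gamma_value
    ka_ph = transform_K_pH(
        ka_meas, reaction.stoichiometry, ladders, record.pH, target_pH
    )
    ka_t = vant_hoff(ka_ph, dRh0_kJ, record.T, target_T)
    dg0 = dg0_from_ka(ka_t, target_T)
    rel_km = record.K_uncertainty / record.K_value if record.K_uncertainty else 0.0
    u_km = R_KJ * target_T * rel_km
    u_kg = R_KJ * target_T * k_gamma_rel_uncertainty
    u_dh = abs(1.0 - target_T / record.T) * dRh0_uncertainty
    return StandardGibbsResult(
        reaction_id=reaction.reaction_id,
        dg0=dg0,
        uncertainty=math.sqrt(u_km**2 + u_kg**2 + u_dh**2),
        T=target_T,
        pH=target_pH,
        details={
            "Km": km,
            "Kgamma": k_gamma_value,
            "Ka_measured": ka_meas,
            "Ka_target_pH": ka_ph,
            "Ka_target_T": ka_t,
            **meta,
        },
    )


# ---------------------------------------------------------------------------
def load_pathway(path: str | Path | None = None) -> list[ReactionSpec]:
    """Load a reaction list (defaults to the bundled glycolysis scheme)."""
    if path is None:
        path = Path(resources.files("actipath").joinpath("data", "glycolysis.yaml"))
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = []
    for entry in doc["reactions"]:
        out.append(
            ReactionSpec(
                reaction_id=str(entry["id"]),
                stoichiometry={str(k): float(v) for k, v in entry["stoichiometry"].items()},
                display_name=str(entry.get("display_name", "")),
                number=entry.get("number"),
            )
        )
    return out


def pathway_species(reactions: list[ReactionSpec]) -> list[str]:
    """All quotient participants of a pathway, in first-appearance order."""
    seen: dict[str, None] = {}
    for rxn in reactions:
        for sp in rxn.participants:
            seen.setdefault(sp)
    return list(seen)
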