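"""Aqueous media: salt dissociation, buffer speciation, electroneutrality.

A :class:`Medium` is a set of solute molalities (mol/kg water) plus T, pH
and pressure.  Salts dissociate into the tabulated ions; buffers are
speciated at the stated pH (Tris/TrisH+ with Cl- closing charge, phosphate
as H2PO4-/HPO4-2 with the declared counter cation).  Electroneutrality is
checked against the tabulated EOS valences; species below trace level are
exempt.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .constants import MW_WATER, P_AMBIENT, molality_to_mole_fractions
from .parameters import ParameterRegistry, default_registry
from .speciation import AcidBaseLadder, acid_fraction, load_pka_table

TRACE_MOLALITY = 5.0e-9  # mol/kg; mole fraction ~ 1e-10

# fully dissociating salts: formula -> {ion: count}
SALTS: dict[str, dict[str, int]] = {
    "KCl": {"K+": 1, "Cl-": 1},
    "NaCl": {"Na+": 1, "Cl-": 1},
    "MgCl2": {"Mg+2": 1, "Cl-": 2},
    "(NH4)2SO4": {"NH4+": 2, "SO4-2": 1},
    "K2SO4": {"K+": 2, "SO4-2": 1},
    "Na2SO4": {"Na+": 2, "SO4-2": 1},
    "MgSO4": {"Mg+2": 1, "SO4-2": 1},
    "KH2PO4": {"K+": 1, "H2PO4-": 1},
    "K2HPO4": {"K+": 2, "HPO4-2": 1},
    "NaH2PO4": {"Na+": 1, "H2PO4-": 1},
    "Na2HPO4": {"Na+": 2, "HPO4-2": 1},
}

BUFFER_COUNTER_ION = {
    "tris_hcl": "Cl-",
    "sodium_phosphate": "Na+",
    "potassium_phosphate": "K+",
}


class MediumError(ValueError):
    pass


@dataclass(frozen=True)
class Medium:
    """Aqueous phase: solute molalities (mol/kg water), T, pH, pressure."""

    label: str
    T: float
    pH: float
    molalities: dict
    P: float = P_AMBIENT

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.molalities.values()):
            raise MediumError(f"{self.label}: negative molality")

    def charge_imbalance(self, registry: ParameterRegistry) -> float:
        """Sum of m_i z_i over non-trace species, mol/kg."""
        return sum(
            m * registry.get(sp).z
            for sp, m in self.molalities.items()
            if m >= 10 * TRACE_MOLALITY
        )

    def check_electroneutral(self, registry: ParameterRegistry, tol: float = 1.0e-10) -> None:
        q = self.charge_imbalance(registry)
        if abs(q) > tol:
            raise MediumError(
                f"{self.label}: electroneutrality cannot be closed with declared "
                f"ions; imbalance {q:+.3e} mol(charge)/kg"
            )

    def mole_fractions(self) -> dict:
        return molality_to_mole_fractions(self.molalities)

    @property
    def x_water(self) -> float:
        n_w = 1.0 / MW_WATER
        return n_w / (n_w + sum(self.molalities.values()))

    def with_solutes(self, extra: dict, label: str | None = None) -> "Medium":
        """New medium with additional solute molalities merged in."""
        mol = dict(self.molalities)
        for sp, m in extra.items():
            mol[sp] = mol.get(sp, 0.0) + m
        return replace(self, molalities=mol, label=label or self.label)

    def to_recipe(self) -> dict:
        return {
            "label": self.label,
            "T": self.T,
            "pH": self.pH,
            "P": self.P,
            "molalities": dict(self.molalities),
        }


def build_medium(
    recipe: dict | str | Path,
    registry: ParameterRegistry | None = None,
    ladders: dict[str, AcidBaseLadder] | None = None,
) -> Medium:
    """Build a speciated, charge-balanced medium from a declared recipe.

    Recipe keys: ``label``, ``T`` (K), ``pH``, optional ``P`` (Pa), optional
    ``salts`` (formula -> mol/kg), optional ``buffers`` (list of
    ``{type, total_molality}``), optional ``molalities`` (explicit per-species
    molalities, passed through).
    """
    if not isinstance(recipe, dict):
        with open(recipe) as fh:
            recipe = yaml.safe_load(fh)
    registry = registry or default_registry()
    ladders = ladders or load_pka_table()
    T = float(recipe["T"])
    pH = float(recipe["pH"])
    mol: dict[str, float] = {}

    def add(sp: str, m: float) -> None:
        if sp not in registry:
            raise MediumError(f"species {sp!r} unknown to the parameter registry")
        mol[sp] = mol.get(sp, 0.0) + m

    for sp, m in (recipe.get("molalities") or {}).items():
        add(sp, float(m))

    for formula, m in (recipe.get("salts") or {}).items():
        ions = SALTS.get(formula)
        if ions is None:
            raise MediumError(f"unknown salt formula {formula!r}")
        for ion, count in ions.items():
            add(ion, count * float(m))

    for buf in recipe.get("buffers") or []:
        btype = buf["type"]
        total = float(buf["total_molality"])
        if btype == "tris_hcl":
            f_acid = acid_fraction(ladders["Tris"], pH)
            add("TrisH+", total * f_acid)
            add("Tris", total * (1.0 - f_acid))
            add("Cl-", total * f_acid)  # declared counter ion
        elif btype in ("sodium_phosphate", "potassium_phosphate"):
            f_acid = acid_fraction(ladders["phosphate"], pH)
            m_h2 = total * f_acid
            m_h1 = total * (1.0 - f_acid)
            add("H2PO4-", m_h2)
            add("HPO4-2", m_h1)
            add(BUFFER_COUNTER_ION[btype], m_h2 + 2.0 * m_h1)
        else:
            raise MediumError(f"unknown buffer type {btype!r}")

    medium = Medium(
        label=str(recipe.get("label", "medium")),
        T=T,
        pH=pH,
        molalities=mol,
        P=float(recipe.get("P", recipe.get("pressure", P_AMBIENT))),
    )
    medium.check_electroneutral(registry, tol=1.0e-10)
    return medium


def close_charge(
    molalities: dict, registry: ParameterRegistry, cation: str = "K+", anion: str = "Cl-"
) -> dict:
    """Close the charge balance of a solute set with a declared counter ion.

    Returns a new molality dict; trace species are ignored in the balance.
    """
    q = sum(
        m * registry.get(sp).z
        for sp, m in molalities.items()
        if m >= 10 * TRACE_MOLALITY
    )
    out = dict(molalities)
    if q < -1.0e-15:
        out[cation] = out.get(cation, 0.0) + abs(q) / registry.get(cation).z
    elif q > 1.0e-15:
        out[anion] = out.get(anion, 0.0) + q / abs(registry.get(anion).z)
    return out


def bundled_medium(name: str, registry: ParameterRegistry | None = None) -> Medium:
    """Load one of the bundled worked-example media (e.g. ``hansen_pfk``)."""
    from importlib import resources

    path = Path(resources.files("actipath").joinpath("data", "media", f"{name}.yaml"))
    if not path.exists():
        raise FileNotFoundError(f"no bundled medium {name!r} at {path}")
    return build_medium(path, registry)
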