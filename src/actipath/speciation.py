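"""Acid-base speciation: Henderson-Hasselbalch ladders, binding polynomials,
and pH transformation of apparent equilibrium constants.

A metabolite's protonation states are indexed by the number of protons
``n`` added to the fully deprotonated reference form (n = 0).  With the
ascending pKa list ``p_1 < ... < p_N``, the relative abundance of state n is

    w_n(pH) = 10^( sum_{j=N-n+1..N} p_j  -  n pH ),

so the binding polynomial P(pH) = sum_n w_n >= 1 is referenced to the fully
deprotonated form.  Apparent (pH-dependent) equilibrium constants transform
between pH values through the binding polynomials of every participant and
the proton activity a_H+ = 10^-pH:

    K(pH2) = K(pH1) * prod_i [P_i(pH2)/P_i(pH1)]^nu_i * 10^(nu_H (pH2-pH1)),

where nu_H > 0 means H+ is *produced* (referenced to the deprotonated
species); raising the pH then pulls the reaction forward and increases the
apparent K.  pKa temperature dependence is neglected over 298.15-311.15 K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

H_PLUS = "H+"


@dataclass(frozen=True)
class AcidBaseLadder:
    """Ordered pKa ladder of one metabolite."""

    metabolite_id: str
    pka_values: tuple = ()  # ascending
    charge_most_protonated: int = 0

    def __post_init__(self) -> None:
        pk = tuple(float(p) for p in self.pka_values)
        if any(b <= a for a, b in zip(pk, pk[1:])):
            raise ValueError(f"{self.metabolite_id}: pKa list must strictly increase")
        object.__setattr__(self, "pka_values", pk)

    def __len__(self) -> int:
        return len(self.pka_values)


@dataclass(frozen=True)
class SpeciesDistribution:
    """Mole fractions over protonation states, most deprotonated first."""

    metabolite_id: str
    pH: float
    fractions: tuple

    def __post_init__(self) -> None:
        s = float(sum(self.fractions))
        if abs(s - 1.0) > 1.0e-12:
            raise ValueError("fractions must sum to 1")


def _state_weights(ladder: AcidBaseLadder, pH: float) -> np.ndarray:
    """log10 relative abundances of states n = 0..N protons added."""
    pk = np.asarray(ladder.pka_values)
    N = pk.size
    # cumulative sum of the largest n pKa values
    cum = np.concatenate([[0.0], np.cumsum(pk[::-1])])
    n = np.arange(N + 1)
    return cum - n * pH


def species_fractions(ladder: AcidBaseLadder, pH: float) -> SpeciesDistribution:
    """Protonation-state distribution at the given pH (binding-polynomial form)."""
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} outside [0, 14]")
    logw = _state_weights(ladder, pH)
    w = 10.0 ** (logw - logw.max())
    return SpeciesDistribution(ladder.metabolite_id, pH, tuple(w / w.sum()))


def binding_polynomial(ladder: AcidBaseLadder, pH: float) -> float:
    """P(pH) >= 1 referenced to the fully deprotonated state."""
    return float(np.sum(10.0 ** _state_weights(ladder, pH)))


def transform_K_pH(
    K_at_pH1: float,
    stoichiometry: dict[str, float],
    ladders: dict[str, AcidBaseLadder],
    pH1: float,
    pH2: float,
) -> float:
    """Move an apparent equilibrium constant from pH1 to pH2.

    ``stoichiometry`` may contain an explicit "H+" entry (nu_H > 0 for H+
    produced); participants without an entry in ``ladders`` are treated as
    pH-insensitive over the window.
    """
    log_k = float(np.log10(K_at_pH1))
    for sp, nu in stoichiometry.items():
        if sp == H_PLUS:
            log_k += nu * (pH2 - pH1)
            continue
        lad = ladders.get(sp)
        if lad is None or len(lad) == 0:
            continue
        log_k += nu * (
            np.log10(binding_polynomial(lad, pH2))
            - np.log10(binding_polynomial(lad, pH1))
        )
    return float(10.0**log_k)


def load_pka_table(path: str | Path | None = None) -> dict[str, AcidBaseLadder]:
    """Load the bundled (or a user) pKa table into ladders."""
    if path is None:
        path = Path(resources.files("actipath").joinpath("data", "pka.csv"))
    df = pd.read_csv(path, comment="#")
    out: dict[str, AcidBaseLadder] = {}
    for _, row in df.iterrows():
        raw = str(row["pka_values"]).strip()
        pkas = tuple(float(v) for v in raw.split(";")) if raw else ()
        out[str(row["metabolite_id"])] = AcidBaseLadder(
            metabolite_id=str(row["metabolite_id"]),
            pka_values=pkas,
            charge_most_protonated=int(row.get("charge_most_protonated", 0)),
        )
    return out


def acid_fraction(ladder: AcidBaseLadder, pH: float) -> float:
    """Fraction of the singly protonated state for a one-pKa ladder.

    Convenience for buffer speciation (TrisH+/Tris, H2PO4-/HPO4-2).
    """
    if len(ladder) != 1:
        raise ValueError("acid_fraction is defined for single-pKa ladders")
    return float(1.0 / (1.0 + 10.0 ** (pH - ladder.pka_values[0])))
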