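"""Two-step thermodynamic feasibility analysis of a pathway.

Conditions A (best case): for each reaction only its own substrates and
products are present — substrates at their maximum, products at their
minimum declared molality — and the activity-coefficient medium contains
nothing else.  A positive dg here means the reaction is infeasible at
*any* concentration ratio within the declared ranges.

Conditions B (cytosol-like): the quotient keeps the conditions-A ratios,
but the activity-coefficient medium additionally contains every other
pathway metabolite at its maximum molality plus the declared salts
(1 mmol/kg MgCl2 + 100 mmol/kg KCl in the bundled file).

Feasibility is strictly dg < 0; dg = 0 is reported as "at equilibrium".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .constants import P_AMBIENT
from .epcsaft import ActivityModel, AssociationError, DensityError
from .media import Medium, close_charge
from .parameters import ParameterRegistry, StandardData, default_registry
from .reaction_thermo import (
    PHOSPHATE,
    ReactionSpec,
    dg0_at_T,
    gibbs_of_reaction,
    reaction_quotient,
)

__all__ = [
    "ConditionSet",
    "FeasibilityReport",
    "best_case_quotient",
    "run_tfa",
    "compare_modes",
    "load_conditions",
]


@dataclass(frozen=True)
class ConditionSet:
    """One TFA scenario."""

    label: str
    T: float
    pH: float
    metabolite_ranges: dict  # species -> (min, max) mol/kg
    salts: dict = field(default_factory=dict)  # formula -> mol/kg
    pressure: float = P_AMBIENT
    mode: str = "activity"  # "activity" | "concentration"
    medium_scope: str = "participants"  # "participants" | "pathway"
    counter_cation: str = "K+"
    counter_anion: str = "Cl-"

    def __post_init__(self) -> None:
        for sp, (lo, hi) in self.metabolite_ranges.items():
            if lo > hi:
                raise ValueError(f"{self.label}: min > max for {sp!r}")
            if lo < 0:
                raise ValueError(f"{self.label}: negative molality for {sp!r}")
        if self.mode not in ("activity", "concentration"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.medium_scope not in ("participants", "pathway"):
            raise ValueError(f"unknown medium_scope {self.medium_scope!r}")

    def replace(self, **kw) -> "ConditionSet":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


def load_conditions(source: str | Path | dict) -> ConditionSet:
    """Load a condition file (bundled labels "A"/"B" or a YAML path)."""
    if isinstance(source, (str, Path)) and str(source) in ("A", "B"):
        source = Path(
            resources.files("actipath").joinpath("data", "conditions", f"{source}.yaml")
        )
    if not isinstance(source, dict):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    ranges = {
        str(sp): (float(lo), float(hi))
        for sp, (lo, hi) in source["metabolite_ranges"].items()
    }
    return ConditionSet(
        label=str(source.get("label", "custom")),
        T=float(source["T"]),
        pH=float(source["pH"]),
        metabolite_ranges=ranges,
        salts={str(k): float(v) for k, v in (source.get("salts") or {}).items()},
        pressure=float(source.get("pressure", P_AMBIENT)),
        mode=str(source.get("mode", "activity")),
        medium_scope=str(source.get("medium_scope", "participants")),
        counter_cation=str(source.get("counter_cation", "K+")),
        counter_anion=str(source.get("counter_anion", "Cl-")),
    )


def best_case_quotient(
    reaction: ReactionSpec, conditions: ConditionSet
) -> tuple[dict, dict]:
    """Best-case molalities: substrates at max, products at min.

    Returns ``(quotient_molalities, gamma_medium_molalities)``; the latter
    adds non-participant metabolites at their maxima when the condition
    set's medium scope is "pathway", and is identical to the former for the
    participants-only scope.
    """
    q_mol: dict[str, float] = {}
    for sp in reaction.participants:
        if sp not in conditions.metabolite_ranges:
            raise KeyError(
                f"{reaction.reaction_id}: no declared range for participant {sp!r}"
            )
        lo, hi = conditions.metabolite_ranges[sp]
        q_mol[sp] = hi if reaction.stoichiometry[sp] < 0 else lo
    gamma_mol = dict(q_mol)
    if conditions.medium_scope == "pathway":
        for sp, (lo, hi) in conditions.metabolite_ranges.items():
            if sp not in gamma_mol:
                gamma_mol[sp] = hi
    return q_mol, gamma_mol


def _base_medium(conditions: ConditionSet, registry: ParameterRegistry) -> Medium:
    from .media import build_medium

    return build_medium(
        {
            "label": conditions.label,
            "T": conditions.T,
            "pH": conditions.pH,
            "P": conditions.pressure,
            "salts": conditions.salts,
        },
        registry,
    )


@dataclass
class FeasibilityReport:
    """Per-reaction dg values and verdicts for one condition set."""

    label: str
    T: float
    pH: float
    mode: str
    rows: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def all_feasible(self) -> bool:
        return all(r.get("feasible") is True for r in self.rows)

    @property
    def indeterminate(self) -> list:
        return [r["reaction_id"] for r in self.rows if r.get("feasible") is None]

    def row(self, reaction_id: str) -> dict:
        for r in self.rows:
            if r["reaction_id"] == reaction_id:
                return r
        raise KeyError(reaction_id)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "reaction_id",
            "number",
            "dRg0_kJmol",
            "lnQ_term_kJmol",
            "Qgamma",
            "dRg_kJmol",
            "feasible",
        ]
        return pd.DataFrame([{c: r.get(c) for c in cols} for r in self.rows])

    def to_json(self, **json_kw) -> str:
        return json.dumps(
            {
                "label": self.label,
                "T": self.T,
                "pH": self.pH,
                "mode": self.mode,
                "all_feasible": self.all_feasible,
                "rows": self.rows,
                "metadata": self.metadata,
            },
            sort_keys=True,
            **json_kw,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeasibilityReport":
        doc = json.loads(text)
        return cls(
            label=doc["label"],
            T=doc["T"],
            pH=doc["pH"],
            mode=doc["mode"],
            rows=doc["rows"],
            metadata=doc.get("metadata", {}),
        )


def run_tfa(
    pathway: list[ReactionSpec],
    standard: dict[str, StandardData],
    conditions: ConditionSet,
    registry: ParameterRegistry | None = None,
    model: ActivityModel | None = None,
) -> FeasibilityReport:
    """Evaluate dg for every pathway reaction under the given conditions."""
    registry = registry or default_registry()
    model = model or ActivityModel(registry)
    missing = [r.reaction_id for r in pathway if r.reaction_id not in standard]
    if missing:
        raise KeyError(f"standard data missing for reactions: {missing}")
    base = _base_medium(conditions, registry)
    report = FeasibilityReport(
        label=conditions.label, T=conditions.T, pH=conditions.pH, mode=conditions.mode
    )
    for rxn in pathway:
        std = standard[rxn.reaction_id]
        dg0 = dg0_at_T(std, conditions.T)
        q_mol, gamma_mol = best_case_quotient(rxn, conditions)
        row: dict = {
            "reaction_id": rxn.reaction_id,
            "number": rxn.number,
            "display_name": rxn.display_name,
            "dRg0_kJmol": dg0,
        }
        try:
            q = reaction_quotient(
                rxn,
                q_mol,
                base,
                registry,
                model,
                mode=conditions.mode,
                h_explicit=std.h_explicit,
                gamma_medium_molalities=gamma_mol,
            )
        except (AssociationError, DensityError) as exc:
            row.update(
                {
                    "feasible": None,
                    "error": str(exc),
                    "Qgamma": None,
                    "lnQ_term_kJmol": None,
                    "dRg_kJmol": None,
                }
            )
            report.rows.append(row)
            continue
        dg = gibbs_of_reaction(dg0, q["Q"], conditions.T)
        row.update(
            {
                "Qm": q["Qm"],
                "Qgamma": q["Qgamma"],
                "lnQ_term_kJmol": dg - dg0,
                "dRg_kJmol": dg,
                "feasible": bool(dg < 0.0),
                "at_equilibrium": bool(dg == 0.0),
            }
        )
        report.rows.append(row)
    report.metadata.update(
        {
            "medium_scope": conditions.medium_scope,
            "salts": dict(conditions.salts),
            "pressure": conditions.pressure,
        }
    )
    return report


def compare_modes(
    pathway: list[ReactionSpec],
    standard: dict[str, StandardData],
    conditions: ConditionSet,
    registry: ParameterRegistry | None = None,
    model: ActivityModel | None = None,
) -> pd.DataFrame:
    """Activity- vs concentration-based dg under identical conditions."""
    registry = registry or default_registry()
    model = model or ActivityModel(registry)
    act = run_tfa(pathway, standard, conditions.replace(mode="activity"), registry, model)
    conc = run_tfa(
        pathway, standard, conditions.replace(mode="concentration"), registry, model
    )
    rows = []
    for ra, rc in zip(act.rows, conc.rows):
        assert ra["reaction_id"] == rc["reaction_id"]
        da, dc = ra.get("dRg_kJmol"), rc.get("dRg_kJmol")
        rows.append(
            {
                "reaction_id": ra["reaction_id"],
                "number": ra.get("number"),
                "dRg_activity_kJmol": da,
                "dRg_concentration_kJmol": dc,
                "Qgamma": ra.get("Qgamma"),
                "sign_disagreement": (
                    None if da is None or dc is None else bool((da < 0) != (dc < 0))
                ),
            }
        )
    return pd.DataFrame(rows)
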