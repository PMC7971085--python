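"""Seeded synthetic condition sets for testing the pipeline end to end.

The generator draws per-metabolite molality ranges and salt loads from a
template spanning the bundled scenarios (metabolites 0.01-20 mmol/kg, KCl
0-300 mmol/kg, MgCl2 0-10 mmol/kg) and returns fully valid
:class:`~actipath.tfa.ConditionSet` objects; media built from them are
electroneutral by construction (salts dissociate stoichiometrically and
charged metabolites are closed by the declared counter ion).
"""

from __future__ import annotations

import numpy as np

from .tfa import ConditionSet

DEFAULT_TEMPLATE = {
    "metabolite_bounds": (1.0e-5, 2.0e-2),  # mol/kg
    "kcl_bounds": (0.0, 0.300),
    "mgcl2_bounds": (0.0, 0.010),
    "T_bounds": (298.15, 311.15),
    "pH_bounds": (6.5, 8.0),
    "metabolites": [
        "glucose", "G6P", "F6P", "FBP", "DHAP", "GAP", "BPG", "3PG", "2PG",
        "PEP", "pyruvate", "ATP", "ADP", "NAD+", "NADH", "phosphate",
    ],
}


def synthesize_conditions(
    seed: int, n_sets: int, ranges_template: dict | None = None
) -> list[ConditionSet]:
    """Generate ``n_sets`` reproducible random condition sets."""
    tpl = {**DEFAULT_TEMPLATE, **(ranges_template or {})}
    rng = np.random.default_rng(seed)
    lo_b, hi_b = tpl["metabolite_bounds"]
    out = []
    for i in range(n_sets):
        ranges = {}
        for sp in tpl["metabolites"]:
            a, b = np.exp(rng.uniform(np.log(lo_b), np.log(hi_b), size=2))
            ranges[sp] = (float(min(a, b)), float(max(a, b)))
        salts = {}
        kcl = float(rng.uniform(*tpl["kcl_bounds"]))
        mgcl2 = float(rng.uniform(*tpl["mgcl2_bounds"]))
        if kcl > 0:
            salts["KCl"] = kcl
        if mgcl2 > 0:
            salts["MgCl2"] = mgcl2
        out.append(
            ConditionSet(
                label=f"synthetic-{seed}-{i}",
                T=float(rng.uniform(*tpl["T_bounds"])),
                pH=float(rng.uniform(*tpl["pH_bounds"])),
                metabolite_ranges=ranges,
                salts=salts,
                mode="activity" if rng.random() < 0.5 else "concentration",
                medium_scope="pathway" if rng.random() < 0.5 else "participants",
            )
        )
    return out
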