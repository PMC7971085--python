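"""Parameter registry: ePC-SAFT pure-component and binary parameters,
standard reaction data, and their plain-text table IO.

All tabulated parameters were transcribed from the typeset source tables;
``data/SCHEMA.md`` documents columns and units.  Parameters are in the
units of the tables (Å, K); everything downstream converts to SI.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

T_WINDOW = (273.0, 373.0)  # validity window for kij(T) and sigma(T), K

# water segment-diameter correlation, sigma(T) = C0 + C1 exp(C2 T) + C3 exp(C4 T)
WATER_SIGMA_COEFFS = (2.7927, 10.11, -0.01775, -1.417, -0.01146)


@dataclass(frozen=True)
class PureComponentParams:
    """One species' ePC-SAFT parameter set."""

    species_id: str
    m_seg: float
    sigma: float  # Å; for water this is the constant of the T-correlation
    u_over_kB: float  # K
    n_donor: int = 0
    n_acceptor: int = 0
    eps_AB_over_kB: float = 0.0  # K
    kappa_AB: float = 0.0
    z: int = 0
    sigma_model: str = "const"  # "const" | "water_exp"
    source: str = ""

    def __post_init__(self) -> None:
        if self.m_seg <= 0:
            raise ValueError(f"{self.species_id}: m_seg must be > 0")
        if self.n_donor < 0 or self.n_acceptor < 0:
            raise ValueError(f"{self.species_id}: negative association site count")
        if not 0.0 <= self.kappa_AB <= 1.0:
            raise ValueError(f"{self.species_id}: kappa_AB must lie in [0, 1]")
        for T in (T_WINDOW[0], 298.15, T_WINDOW[1]):
            if self.sigma_at(T) <= 0:
                raise ValueError(f"{self.species_id}: sigma <= 0 at T = {T} K")

    @property
    def has_assoc_sites(self) -> bool:
        return (self.n_donor + self.n_acceptor) > 0 and self.kappa_AB > 0

    @property
    def is_bare_ion(self) -> bool:
        """Charged species without association sites (simple salt ions).

        These carry a temperature-independent hard-sphere diameter.
        """
        return self.z != 0 and (self.n_donor + self.n_acceptor) == 0

    def sigma_at(self, T: float) -> float:
        """Segment diameter in Å, temperature-dependent only for water."""
        if self.sigma_model == "water_exp":
            c0, c1, c2, c3, c4 = WATER_SIGMA_COEFFS
            return c0 + c1 * math.exp(c2 * T) + c3 * math.exp(c4 * T)
        return self.sigma

    def d_at(self, T: float) -> float:
        """Temperature-dependent hard-sphere segment diameter, Å."""
        sig = self.sigma_at(T)
        if self.is_bare_ion:
            return sig
        return sig * (1.0 - 0.12 * math.exp(-3.0 * self.u_over_kB / T))


@dataclass(frozen=True)
class BinaryInteraction:
    """Dispersion correction kij(T) = kij_t0 + kij_slope * T for one pair."""

    species_pair: frozenset
    kij_slope: float  # 1/K
    kij_t0: float
    source: str = ""

    def at(self, T: float) -> float:
        return self.kij_t0 + self.kij_slope * T


@dataclass(frozen=True)
class StandardData:
    """Standard reaction data at 298.15 K and pH 7."""

    reaction_id: str
    dRg0: float  # kJ/mol
    dRg0_uncertainty: float = 0.0
    dRh0: float = 0.0  # kJ/mol, treated as T-independent 298.15-310.15 K
    dRh0_uncertainty: float = 0.0
    h_explicit: bool = False
    provenance: str = ""


class ParameterRegistry:
    """Lookup table for pure-component, binary and standard-data parameters."""

    def __init__(
        self,
        pure: dict[str, PureComponentParams],
        binary: dict[frozenset, BinaryInteraction] | None = None,
        standard: dict[str, StandardData] | None = None,
    ) -> None:
        self.pure = dict(pure)
        self.binary = dict(binary or {})
        self.standard = dict(standard or {})
        self._warned_pairs: set[frozenset] = set()
        for pair in self.binary:
            for sp in pair:
                if sp not in self.pure:
                    raise ValueError(f"binary pair references unknown species {sp!r}")

    # -- lookups ---------------------------------------------------------
    def __contains__(self, species_id: str) -> bool:
        return species_id in self.pure

    def get(self, species_id: str) -> PureComponentParams:
        return self.pure[species_id]

    def kij(self, sp_i: str, sp_j: str, T: float) -> float:
        """kij(T); symmetric in pair order; 0 (with a logged notice) if absent."""
        if not T_WINDOW[0] <= T <= T_WINDOW[1]:
            warnings.warn(
                f"T = {T} K outside kij validity window {T_WINDOW}", stacklevel=2
            )
        if sp_i == sp_j:
            return 0.0
        pair = frozenset((sp_i, sp_j))
        entry = self.binary.get(pair)
        if entry is None:
            if pair not in self._warned_pairs:
                logger.info("no binary parameters for pair %s; using kij = 0", set(pair))
                self._warned_pairs.add(pair)
            return 0.0
        return entry.at(T)

    def species_ids(self) -> list[str]:
        return list(self.pure)

    def missing_species(self, required: list[str] | set[str]) -> list[str]:
        """Exact list of required species without a pure-parameter row."""
        return sorted(sp for sp in set(required) if sp not in self.pure)

    # -- IO ---------------------------------------------------------------
    def to_tables(self, pure_path: str | Path, binary_path: str | Path) -> None:
        """Write the registry back to the bundled table format (round-trips)."""
        prows = [
            {
                "species_id": p.species_id,
                "m_seg": repr(p.m_seg),
                "sigma": repr(p.sigma),
                "u_over_kB": repr(p.u_over_kB),
                "n_donor": p.n_donor,
                "n_acceptor": p.n_acceptor,
                "eps_AB_over_kB": repr(p.eps_AB_over_kB),
                "kappa_AB": repr(p.kappa_AB),
                "z": p.z,
                "sigma_model": p.sigma_model,
                "source": p.source,
            }
            for p in self.pure.values()
        ]
        pd.DataFrame(prows).to_csv(pure_path, index=False)
        brows = []
        for pair, b in self.binary.items():
            i, j = sorted(pair)
            brows.append(
                {
                    "species_i": i,
                    "species_j": j,
                    "kij_slope": repr(b.kij_slope),
                    "kij_t0": repr(b.kij_t0),
                    "source": b.source,
                }
            )
        pd.DataFrame(brows).to_csv(binary_path, index=False)


def _data_path(name: str) -> Path:
    return Path(resources.files("actipath").joinpath("data", name))


def load_parameter_registry(
    pure_table: str | Path | None = None,
    binary_table: str | Path | None = None,
    standard_table: str | Path | None = None,
) -> ParameterRegistry:
    """Load the parameter registry from plain-text tables.

    Defaults to the bundled tables.  Hard failures name the offending row.
    """
    pure_table = pure_table or _data_path("pure.csv")
    binary_table = binary_table or _data_path("binary.csv")
    standard_table = standard_table or _data_path("standard_data.csv")

    pure_df = pd.read_csv(pure_table, comment="#")
    pure: dict[str, PureComponentParams] = {}
    for idx, row in pure_df.iterrows():
        sp = str(row["species_id"])
        if sp in pure:
            raise ValueError(f"duplicate species {sp!r} in {pure_table} (row {idx})")
        try:
            pure[sp] = PureComponentParams(
                species_id=sp,
                m_seg=float(row["m_seg"]),
                sigma=float(row["sigma"]),
                u_over_kB=float(row["u_over_kB"]),
                n_donor=int(row["n_donor"]),
                n_acceptor=int(row["n_acceptor"]),
                eps_AB_over_kB=float(row.get("eps_AB_over_kB", 0.0) or 0.0),
                kappa_AB=float(row.get("kappa_AB", 0.0) or 0.0),
                z=int(row["z"]),
                sigma_model=str(row.get("sigma_model", "const")),
                source=str(row.get("source", "")),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"malformed pure-parameter row {idx} ({sp!r}) in {pure_table}: {exc}"
            ) from exc

    binary: dict[frozenset, BinaryInteraction] = {}
    bin_df = pd.read_csv(binary_table, comment="#")
    for idx, row in bin_df.iterrows():
        i, j = str(row["species_i"]), str(row["species_j"])
        pair = frozenset((i, j))
        for sp in (i, j):
            if sp not in pure:
                raise ValueError(
                    f"binary row {idx} in {binary_table} references unknown species {sp!r}"
                )
        try:
            entry = BinaryInteraction(
                species_pair=pair,
                kij_slope=float(row["kij_slope"]),
                kij_t0=float(row["kij_t0"]),
                source=str(row.get("source", "")),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"malformed binary row {idx} ({i}/{j}) in {binary_table}: {exc}"
            ) from exc
        for T in T_WINDOW:
            if not -2.0 <= entry.at(T) <= 2.0 or not math.isfinite(entry.at(T)):
                raise ValueError(
                    f"kij({i}/{j}) = {entry.at(T)} outside [-2, 2] at T = {T} K"
                )
        binary[pair] = entry

    standard: dict[str, StandardData] = {}
    if standard_table is not None and Path(standard_table).exists():
        std_df = pd.read_csv(standard_table, comment="#")
        for idx, row in std_df.iterrows():
            rid = str(row["reaction_id"])
            standard[rid] = StandardData(
                reaction_id=rid,
                dRg0=float(row["dRg0"]),
                dRg0_uncertainty=float(row.get("dRg0_uncertainty", 0.0) or 0.0),
                dRh0=float(row["dRh0"]),
                dRh0_uncertainty=float(row.get("dRh0_uncertainty", 0.0) or 0.0),
                h_explicit=bool(row.get("h_explicit", False)),
                provenance=str(row.get("provenance", "")),
            )

    return ParameterRegistry(pure, binary, standard)


_default_registry: ParameterRegistry | None = None


def default_registry() -> ParameterRegistry:
    """The bundled parameter registry (cached)."""
    global _default_registry
    if _default_registry is None:
        _default_registry = load_parameter_registry()
    return _default_registry


def kij_at_T(registry: ParameterRegistry, sp_i: str, sp_j: str, T: float) -> float:
    """Module-level convenience wrapper over :meth:`ParameterRegistry.kij`."""
    return registry.kij(sp_i, sp_j, T)
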