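"""Electrolyte PC-SAFT equation of state.

Residual Helmholtz energy as the sum of hard-chain, dispersion, association
and Coulomb (Debye-Hueckel) contributions; density solution at given (T, P);
fugacity coefficients from composition derivatives; asymmetric activity
coefficients referenced to infinite dilution in pure water.

Conventions
-----------
* Reduced residual Helmholtz energy ``a = A_res/(N kB T)`` per molecule.
* Number densities in molecules/Å^3 internally; pressures in Pa.
* Temperature-dependent segment diameter d = sigma (1 - 0.12 exp(-3 u/kT))
  for molecular species; bare ions (no association sites) keep d = sigma.
* Dispersion energy u_ij = sqrt(u_i u_j) (1 - kij(T)), switched off between
  like-charged species.
* Cross association by Wolbach-Sandler combining rules: arithmetic-mean
  energy, geometric-mean volume with a segment-diameter correction.  A
  species with eps_AB = 0 but kappa_AB > 0 does not self-associate but does
  cross-associate (induced association).
* Ion term: Debye-Hueckel with the static permittivity of pure water
  (Malmberg-Maryott correlation); ion diameter sigma_j.

Derivatives of ``a`` with respect to density and composition are taken by
complex-step differentiation, which is exact to machine precision for the
analytic expressions used here; central finite differences serve as the
independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import (
    ANGSTROM,
    EPS0,
    E_CHARGE,
    KB,
    bjerrum_length,
    water_relative_permittivity,
)
from .parameters import ParameterRegistry

__all__ = [
    "EPCSAFT",
    "MixtureState",
    "HelmholtzBreakdown",
    "AssociationError",
    "DensityError",
    "residual_helmholtz",
]

ETA_MAX = 0.74  # close-packing bound on the packing fraction
ASSOC_TOL = 1.0e-12
ASSOC_MAX_ITER = 500
ASSOC_DAMPING = 0.5
CSTEP = 1.0e-100  # complex-step size
TRACE_X = 1.0e-10  # operational infinite-dilution mole fraction

# PC-SAFT universal dispersion constants
_A = np.array(
    [
        [0.91056314451778, -0.30840169182720, -0.09061483509767],
        [0.63612814494991, 0.18605311591713, 0.45278428063920],
        [2.68613478913903, -2.50300472586548, 0.59627007280101],
        [-26.5473624914884, 21.4197936296668, -1.72418291311787],
        [97.7592087835073, -65.2558853303492, -4.13021125311661],
        [-159.591540865600, 83.3186804808856, 13.7766318697211],
        [91.2977740839123, -33.7469229297323, -8.67284703679646],
    ]
)
_B = np.array(
    [
        [0.72409469413165, -0.57554980753450, 0.09768831158356],
        [2.23827918609380, 0.69950955214436, -0.25575749816100],
        [-4.00258494846342, 3.89256733895307, -9.15585615297321],
        [-21.0035768148465, -17.2154716477721, 20.6420757915584],
        [26.8556413626615, 192.672264465249, -38.8044300520627],
        [206.551338406619, -161.826461648765, 93.6267740770146],
        [-355.602356122079, -165.207693455561, -29.6669055851473],
    ]
)


class AssociationError(RuntimeError):
    """Association fixed point did not converge; carries the residual norm."""

    def __init__(self, residual: float):
        super().__init__(
            f"association site fractions not converged within {ASSOC_MAX_ITER} "
            f"iterations (residual {residual:.3e})"
        )
        self.residual = residual


class DensityError(RuntimeError):
    """No density root found on the hinted branch."""


@dataclass(frozen=True)
class HelmholtzBreakdown:
    """Residual Helmholtz contributions, A/(N kB T)."""

    a_hc: float
    a_disp: float
    a_assoc: float
    a_ion: float

    @property
    def a_res(self) -> float:
        return self.a_hc + self.a_disp + self.a_assoc + self.a_ion


@dataclass(frozen=True)
class MixtureState:
    """A converged single-phase aqueous state."""

    T: float  # K
    P: float  # Pa
    species: tuple
    x: np.ndarray  # mole fractions
    rho: float  # molecules / Å^3

    @property
    def composition(self) -> dict:
        return dict(zip(self.species, self.x))


def _chi(t):
    """Shape factor of the Debye-Hueckel term, chi(kappa a) =
    (3/t^3) [ln(1+t) - t + t^2/2], with a series guard against cancellation."""
    t = np.asarray(t)
    small = np.abs(t) < 0.01
    safe = np.where(small, 1.0, t)
    full = 3.0 / safe**3 * (np.log(1.0 + safe) - safe + 0.5 * safe**2)
    series = 3.0 * (
        1.0 / 3.0 - t / 4.0 + t**2 / 5.0 - t**3 / 6.0 + t**4 / 7.0 - t**5 / 8.0
    )
    return np.where(small, series, full)


class EPCSAFT:
    """ePC-SAFT model for a fixed species list against a parameter registry."""

    def __init__(self, registry: ParameterRegistry, species: list[str]):
        missing = registry.missing_species(species)
        if missing:
            raise KeyError(f"species without pure parameters: {missing}")
        self.registry = registry
        self.species = tuple(species)
        ps = [registry.get(sp) for sp in species]
        self.m = np.array([p.m_seg for p in ps])
        self.u = np.array([p.u_over_kB for p in ps])
        self.z = np.array([float(p.z) for p in ps])
        self.nd = np.array([float(p.n_donor) for p in ps])
        self.na = np.array([float(p.n_acceptor) for p in ps])
        self.eps = np.array([p.eps_AB_over_kB for p in ps])
        self.kap = np.array([p.kappa_AB for p in ps])
        self._assoc_mask = np.array([p.has_assoc_sites for p in ps])
        self._params = ps
        self._tcache_T: float | None = None
        self._phi_inf_cache: dict = {}

    # ------------------------------------------------------------------
    def _tcache(self, T: float) -> dict:
        if self._tcache_T == T:
            return self._tc
        sig = np.array([p.sigma_at(T) for p in self._params])
        d = np.array([p.d_at(T) for p in self._params])
        sig_ij = 0.5 * (sig[:, None] + sig[None, :])
        kij = np.zeros_like(sig_ij)
        n = len(self.species)
        for i in range(n):
            for j in range(i + 1, n):
                kij[i, j] = kij[j, i] = self.registry.kij(
                    self.species[i], self.species[j], T
                )
        u_ij = np.sqrt(np.outer(self.u, self.u)) * (1.0 - kij)
        # dispersion between two charged species only where a binary kij was
        # fitted (salt cation-anion pairs); never between like charges
        charged = self.z != 0.0
        fitted = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(n):
                if i != j and frozenset(
                    (self.species[i], self.species[j])
                ) in self.registry.binary:
                    fitted[i, j] = True
        u_ij[np.outer(charged, charged) & ~fitted] = 0.0
        u_ij[np.outer(self.z, self.z) > 0] = 0.0
        # dispersion building blocks Sum x_i x_j m_i m_j (u_ij/T)^p sigma_ij^3
        mm_s3 = np.outer(self.m, self.m) * sig_ij**3
        disp1 = mm_s3 * (u_ij / T)
        disp2 = mm_s3 * (u_ij / T) ** 2
        # association: Wolbach-Sandler cross parameters
        amask = self._assoc_mask
        aidx = np.nonzero(amask)[0]
        if aidx.size:
            eps_c = 0.5 * (self.eps[aidx, None] + self.eps[None, aidx])
            kap_c = np.sqrt(np.outer(self.kap[aidx], self.kap[aidx])) * (
                np.sqrt(np.outer(sig[aidx], sig[aidx]))
                / (0.5 * (sig[aidx, None] + sig[None, aidx]))
            ) ** 3
            s3 = (0.5 * (sig[aidx, None] + sig[None, aidx])) ** 3
            delta_base = s3 * kap_c * np.expm1(eps_c / T)
        else:
            delta_base = np.zeros((0, 0))
        self._tc = {
            "T": T,
            "sig": sig,
            "d": d,
            "disp1": disp1,
            "disp2": disp2,
            "aidx": aidx,
            "delta_base": delta_base,
            "lambda_b": bjerrum_length(T),
            "kappa_coeff": E_CHARGE**2
            / (EPS0 * water_relative_permittivity(T) * KB * T),
        }
        self._tcache_T = T
        return self._tc

    # ------------------------------------------------------------------
    def _g_hs(self, dmat_i, dmat_j, z2, z3):
        dd = dmat_i * dmat_j / (dmat_i + dmat_j)
        om = 1.0 - z3
        return 1.0 / om + dd * 3.0 * z2 / om**2 + dd**2 * 2.0 * z2**2 / om**3

    def _solve_site_fractions(self, tc, rho, x):
        """Damped successive substitution for the Wertheim site fractions."""
        aidx = tc["aidx"]
        if aidx.size == 0:
            return None
        d = tc["d"]
        z2 = np.pi / 6.0 * rho * np.sum(x * self.m * d**2)
        z3 = np.pi / 6.0 * rho * np.sum(x * self.m * d**3)
        di = d[aidx]
        g = self._g_hs(di[:, None], di[None, :], z2, z3)
        delta = g * tc["delta_base"]
        xa_sp = x[aidx]
        nd, na = self.nd[aidx], self.na[aidx]
        dtype = np.result_type(rho, x, float)
        Xd = np.full(aidx.size, 0.2, dtype=dtype)
        Xa = np.full(aidx.size, 0.2, dtype=dtype)
        lam = ASSOC_DAMPING
        for _ in range(ASSOC_MAX_ITER):
            Xd_new = 1.0 / (1.0 + rho * (delta @ (xa_sp * na * Xa)))
            Xa_new = 1.0 / (1.0 + rho * (delta.T @ (xa_sp * nd * Xd)))
            err = max(
                float(np.max(np.abs(Xd_new - Xd))), float(np.max(np.abs(Xa_new - Xa)))
            )
            Xd = (1.0 - lam) * Xd + lam * Xd_new
            Xa = (1.0 - lam) * Xa + lam * Xa_new
            if err < ASSOC_TOL:
                return Xd, Xa
        raise AssociationError(err)

    def site_fractions(self, T: float, rho: float, x: np.ndarray):
        """Converged site fractions (donor, acceptor) per associating species."""
        tc = self._tcache(T)
        out = self._solve_site_fractions(tc, float(rho), np.asarray(x, dtype=float))
        if out is None:
            return {}, np.array([]), np.array([])
        Xd, Xa = out
        names = [self.species[i] for i in tc["aidx"]]
        return names, Xd, Xa

    def site_fraction_residual(self, T: float, rho: float, x: np.ndarray) -> float:
        """Mass-action residual of the converged site fractions (test hook)."""
        tc = self._tcache(T)
        out = self._solve_site_fractions(tc, float(rho), np.asarray(x, dtype=float))
        if out is None:
            return 0.0
        Xd, Xa = out
        aidx = tc["aidx"]
        d = tc["d"]
        z2 = np.pi / 6.0 * rho * np.sum(x * self.m * d**2)
        z3 = np.pi / 6.0 * rho * np.sum(x * self.m * d**3)
        di = d[aidx]
        g = self._g_hs(di[:, None], di[None, :], z2, z3)
        delta = g * tc["delta_base"]
        xa_sp = x[aidx]
        r1 = Xd - 1.0 / (1.0 + rho * (delta @ (xa_sp * self.na[aidx] * Xa)))
        r2 = Xa - 1.0 / (1.0 + rho * (delta.T @ (xa_sp * self.nd[aidx] * Xd)))
        return float(max(np.max(np.abs(r1)), np.max(np.abs(r2))))

    # ------------------------------------------------------------------
    def _a_terms(self, T: float, rho, x):
        """Residual Helmholtz contributions; rho and x may be complex.

        All expressions are written literally in the mole fractions, so
        composition derivatives taken with the other x_j held fixed (the
        convention of the fugacity-coefficient formula) are meaningful for
        unnormalized perturbations.
        """
        tc = self._tcache(T)
        d = tc["d"]
        m = self.m
        z0 = np.pi / 6.0 * rho * np.sum(x * m)
        z1 = np.pi / 6.0 * rho * np.sum(x * m * d)
        z2 = np.pi / 6.0 * rho * np.sum(x * m * d**2)
        z3 = np.pi / 6.0 * rho * np.sum(x * m * d**3)
        om = 1.0 - z3

        # hard chain (Boublik-Mansoori hard-sphere mixture + chain connectivity)
        a_hs = (
            3.0 * z1 * z2 / om
            + z2**3 / (z3 * om**2)
            + (z2**3 / z3**2 - z0) * np.log(om)
        ) / z0
        g_ii = self._g_hs(d, d, z2, z3)
        mbar = np.sum(x * m)
        a_hc = mbar * a_hs - np.sum(x * (m - 1.0) * np.log(g_ii))

        # dispersion (universal-constant power series)
        eta = z3
        mr = (mbar - 1.0) / mbar
        mr2 = mr * (mbar - 2.0) / mbar
        ai = _A[:, 0] + mr * _A[:, 1] + mr2 * _A[:, 2]
        bi = _B[:, 0] + mr * _B[:, 1] + mr2 * _B[:, 2]
        powers = eta ** np.arange(7)
        I1 = np.sum(ai * powers)
        I2 = np.sum(bi * powers)
        C1 = 1.0 / (
            1.0
            + mbar * (8.0 * eta - 2.0 * eta**2) / om**4
            + (1.0 - mbar)
            * (20.0 * eta - 27.0 * eta**2 + 12.0 * eta**3 - 2.0 * eta**4)
            / (om * (2.0 - eta)) ** 2
        )
        m2es3 = x @ tc["disp1"] @ x
        m2e2s3 = x @ tc["disp2"] @ x
        a_disp = (
            -2.0 * np.pi * rho * I1 * m2es3 - np.pi * rho * mbar * C1 * I2 * m2e2s3
        )

        # association (Wertheim first-order theory)
        a_assoc = 0.0 * rho
        out = self._solve_site_fractions(tc, rho, x)
        if out is not None:
            Xd, Xa = out
            aidx = tc["aidx"]
            contrib = self.nd[aidx] * (np.log(Xd) - 0.5 * Xd + 0.5) + self.na[aidx] * (
                np.log(Xa) - 0.5 * Xa + 0.5
            )
            a_assoc = np.sum(x[aidx] * contrib)

        # Coulomb interactions (Debye-Hueckel)
        a_ion = 0.0 * rho
        if np.any(self.z != 0.0):
            xz2 = np.sum(x * self.z**2)
            if np.any(np.asarray(x * self.z**2) != 0.0):
                kappa = np.sqrt(tc["kappa_coeff"] * rho * 1.0e30 * xz2)
                t = kappa * tc["sig"] * ANGSTROM
                chi = _chi(t)
                a_ion = -kappa * tc["lambda_b"] / 3.0 * np.sum(x * self.z**2 * chi)

        return a_hc, a_disp, a_assoc, a_ion

    def a_res(self, T: float, rho, x):
        """Reduced residual Helmholtz energy a = A/(N kB T)."""
        a_hc, a_disp, a_assoc, a_ion = self._a_terms(T, rho, np.asarray(x))
        return a_hc + a_disp + a_assoc + a_ion

    def helmholtz_breakdown(self, T: float, rho: float, x: np.ndarray) -> HelmholtzBreakdown:
        a_hc, a_disp, a_assoc, a_ion = self._a_terms(
            T, float(rho), np.asarray(x, dtype=float)
        )
        return HelmholtzBreakdown(
            float(a_hc), float(a_disp), float(a_assoc), float(a_ion)
        )

    # ------------------------------------------------------------------
    def compressibility(self, T: float, rho: float, x: np.ndarray) -> float:
        """Z = 1 + rho d(a_res)/d(rho) by complex-step differentiation."""
        da = self.a_res(T, rho + 1j * CSTEP * rho, np.asarray(x, dtype=float))
        return 1.0 + float(np.imag(da) / (CSTEP * rho) * rho)

    def pressure(self, T: float, rho: float, x: np.ndarray) -> float:
        """Pressure in Pa at number density rho (molecules/Å^3)."""
        Z = self.compressibility(T, rho, x)
        return Z * rho * 1.0e30 * KB * T

    def pressure_fd(self, T: float, rho: float, x: np.ndarray, rel_step: float = 1.0e-6) -> float:
        """Pressure with the density derivative by central finite differences."""
        h = rel_step * rho
        x = np.asarray(x, dtype=float)
        da = (self.a_res(T, rho + h, x) - self.a_res(T, rho - h, x)) / (2.0 * h)
        Z = 1.0 + rho * float(np.real(da))
        return Z * rho * 1.0e30 * KB * T

    # ------------------------------------------------------------------
    def packing_fraction(self, T: float, rho: float, x: np.ndarray) -> float:
        tc = self._tcache(T)
        return float(np.pi / 6.0 * rho * np.sum(x * self.m * tc["d"] ** 3))

    def _check_neutrality(self, x: np.ndarray) -> None:
        major = x >= 1.0e-8  # trace species exempt from the charge balance
        q = float(np.sum(x[major] * self.z[major]))
        if abs(q) > 1.0e-10:
            raise ValueError(
                f"composition not electroneutral: sum x_i z_i = {q:.3e} "
                f"(species {self.species})"
            )

    def solve_density(
        self, T: float, P: float, x: np.ndarray, phase_hint: str = "liquid"
    ) -> MixtureState:
        """Density root at (T, P) on the hinted branch.

        Brackets sign changes of P(eta) - P on a packing-fraction grid and
        polishes with Brent's method; the liquid hint selects the densest
        bracket, the vapor hint the most dilute one.
        """
        x = np.asarray(x, dtype=float)
        if abs(x.sum() - 1.0) > 1.0e-12:
            raise ValueError("mole fractions must sum to 1")
        self._check_neutrality(x)
        tc = self._tcache(T)
        md3 = float(np.sum(x * self.m * tc["d"] ** 3))

        def rho_of_eta(eta: float) -> float:
            return 6.0 * eta / (np.pi * md3)

        def f(eta: float) -> float:
            return self.pressure(T, rho_of_eta(eta), x) - P

        # ideal-gas packing fraction sets the dilute end of the search grid
        eta_ideal = np.pi / 6.0 * (P / (KB * T) * 1.0e-30) * md3
        eta_lo = min(1.0e-12, max(1.0e-3 * eta_ideal, 1.0e-30))
        etas = np.concatenate(
            [np.geomspace(eta_lo, 0.05, 30), np.linspace(0.055, 0.72, 60)]
        )
        vals = np.array([f(e) for e in etas])
        brackets = [
            (etas[i], etas[i + 1])
            for i in range(len(etas) - 1)
            if np.isfinite(vals[i]) and np.isfinite(vals[i + 1])
            and np.sign(vals[i]) != np.sign(vals[i + 1])
        ]
        if not brackets:
            raise DensityError(
                f"no density root for T={T} K, P={P} Pa on grid eta in "
                f"[{etas[0]:.1e}, {etas[-1]:.2f}]; P(eta)-P spans "
                f"[{vals.min():.3e}, {vals.max():.3e}] Pa"
            )
        lo, hi = brackets[-1] if phase_hint == "liquid" else brackets[0]
        eta_root = brentq(f, lo, hi, xtol=1.0e-16, rtol=8.9e-16, maxiter=200)
        rho = rho_of_eta(eta_root)
        resid = abs(self.pressure(T, rho, x) - P) / max(abs(P), 1.0)
        if resid > 1.0e-8:
            raise DensityError(f"density root residual {resid:.3e} exceeds 1e-8")
        if eta_root >= ETA_MAX:
            raise DensityError(f"packing fraction {eta_root:.3f} >= {ETA_MAX}")
        return MixtureState(T=T, P=P, species=self.species, x=x, rho=rho)

    # ------------------------------------------------------------------
    def ln_phi(self, T: float, rho: float, x: np.ndarray) -> np.ndarray:
        """ln fugacity coefficients at a converged state (complex-step)."""
        x = np.asarray(x, dtype=float)
        a0 = float(np.real(self.a_res(T, rho, x)))
        Z = self.compressibility(T, rho, x)
        n = x.size
        dadx = np.empty(n)
        for k in range(n):
            xc = x.astype(complex)
            xc[k] += 1j * CSTEP
            dadx[k] = float(np.imag(self.a_res(T, rho, xc)) / CSTEP)
        mu_res = a0 + (Z - 1.0) + dadx - float(np.sum(x * dadx))
        return mu_res - np.log(Z)

    def ln_phi_fd(self, T: float, rho: float, x: np.ndarray, step: float = 1.0e-6) -> np.ndarray:
        """ln fugacity coefficients with central-difference composition
        derivatives (independent cross-check of :meth:`ln_phi`)."""
        x = np.asarray(x, dtype=float)
        a0 = float(np.real(self.a_res(T, rho, x)))
        Z = self.compressibility(T, rho, x)
        n = x.size
        dadx = np.empty(n)
        for k in range(n):
            xp, xm = x.copy(), x.copy()
            xp[k] += step
            xm[k] -= step
            dadx[k] = float(
                np.real(self.a_res(T, rho, xp) - self.a_res(T, rho, xm)) / (2 * step)
            )
        mu_res = a0 + (Z - 1.0) + dadx - float(np.sum(x * dadx))
        return mu_res - np.log(Z)

    def ln_phi_at_TP(
        self, T: float, P: float, x: np.ndarray, phase_hint: str = "liquid"
    ) -> tuple[MixtureState, np.ndarray]:
        state = self.solve_density(T, P, x, phase_hint)
        return state, self.ln_phi(T, state.rho, x)


# ----------------------------------------------------------------------
def residual_helmholtz(state: MixtureState, registry: ParameterRegistry) -> HelmholtzBreakdown:
    """Residual Helmholtz breakdown of a mixture state."""
    eos = EPCSAFT(registry, list(state.species))
    return eos.helmholtz_breakdown(state.T, state.rho, state.x)


class ActivityModel:
    """Asymmetric activity coefficients gamma* in aqueous media.

    gamma*_i = phi_i(mixture) / phi_i(infinitely diluted in pure water) at
    the same T and P; the molality-scale coefficient is gamma*_m,i =
    gamma*_i x_water.  Infinite dilution is realized at trace mole fraction
    ``TRACE_X`` (1e-10) and the reference values are cached per (species, T, P).
    """

    def __init__(self, registry: ParameterRegistry):
        self.registry = registry
        self._phi_inf: dict = {}
        self._eos_cache: dict = {}

    def _eos(self, species: tuple) -> EPCSAFT:
        if species not in self._eos_cache:
            self._eos_cache[species] = EPCSAFT(self.registry, list(species))
        return self._eos_cache[species]

    def ln_phi_infinite_dilution(
        self, species_id: str, T: float, P: float, trace_x: float = TRACE_X
    ) -> float:
        key = (species_id, T, P, trace_x)
        if key not in self._phi_inf:
            eos = self._eos(("water", species_id))
            x = np.array([1.0 - trace_x, trace_x])
            _, lnphi = eos.ln_phi_at_TP(T, P, x, "liquid")
            self._phi_inf[key] = float(lnphi[1])
        return self._phi_inf[key]

    def gamma_star(
        self,
        T: float,
        P: float,
        composition: dict[str, float],
        species: list[str] | None = None,
        molality_scale: bool = True,
        trace_x: float = TRACE_X,
    ) -> dict[str, float]:
        """gamma* of ``species`` (default: all solutes) in the given mixture.

        ``composition``: mole fractions by species id, water included.
        """
        if "water" not in composition:
            raise ValueError("reference state undefined: water absent from composition")
        ids = tuple(composition)
        eos = self._eos(ids)
        x = np.array([composition[s] for s in ids])
        x = x / x.sum()
        state = eos.solve_density(T, P, x, "liquid")
        lnphi = eos.ln_phi(T, state.rho, x)
        xw = float(x[ids.index("water")])
        targets = species if species is not None else [s for s in ids if s != "water"]
        out = {}
        for sp in targets:
            ln_inf = self.ln_phi_infinite_dilution(sp, T, P, trace_x)
            g = float(np.exp(lnphi[ids.index(sp)] - ln_inf))
            out[sp] = g * xw if molality_scale else g
        return out
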