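"""Perturbed-chain SAFT equation of state for drug-polymer mixtures.

The residual Helmholtz energy per molecule, a_res = a_hc + a_disp +
a_assoc, sums a hard-chain reference (Boublik-Mansoori-Carnahan-Starling
hard-sphere mixture plus chain connectivity), a second-order dispersion
perturbation with the standard universal model constants, and a Wertheim
first-order association term.  Combining rules are conventional:
sigma_ij = (sigma_i + sigma_j)/2 and eps_ij = sqrt(eps_i eps_j)(1 - k_ij),
with the binary correction k_ij optionally linear in temperature.
Cross-association uses the Wolbach-Sandler rules (arithmetic-mean
association energy, geometric-mean association volume with the sigma
correction), which switches on induced association when only one partner
self-associates.

Association sites: the tabulated site count N_assoc of each component is
split equally into donors and acceptors (fractional halves allowed); by
that symmetry every site type on a component shares one fraction of
unbonded sites X_i, solved by a vectorized Newton iteration.

All composition arguments are mole fractions on a whole-molecule basis
(each polymer is a single pseudo-component at its nominal molar mass);
number densities are in particles per cubic angstrom.  Density and
chemical-potential derivatives are taken by the complex-step method,
exact to machine precision through the (holomorphic) term algebra
including the association solve; tests cross-check them against central
finite differences.

Solid-liquid equilibrium of the crystalline drug follows

    x = (1/gamma(x)) exp[-dHfus/(RT) (1 - T/Tm)
                         - dCp/R (1 - Tm/T + ln(Tm/T))]

solved for x at fixed T by damped fixed-point iteration (bracketed
bisection as the fallback and as an independent oracle route), or for T
at fixed x by bracketed root finding on the isotherm residual.
Liquid-liquid coexistence solves the two isoactivity equations
x_i^L1 gamma_i^L1 = x_i^L2 gamma_i^L2 with spinodal-straddling starting
values and continuation in temperature.  Everything is evaluated at a
1 bar reference pressure (results in the incompressible-liquid regime are
insensitive to it), and the pure subcooled liquid drug is the activity
reference at every temperature.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize

from .core import R, CompoundThermo, FitReport, MPDDataset, convert_composition

__all__ = [
    "PcSaftParams",
    "KijModel",
    "PcSaftState",
    "LLEResult",
    "Mixture",
    "activity_coefficients",
    "ideal_solubility",
    "sle_solubility",
    "sle_temperature",
    "lle_point",
    "lle_curve",
    "spinodal_window",
    "fit_kij",
    "load_pcsaft_params",
]

KB = 1.380649e-23  # J/K
NAV = 6.02214076e23  # 1/mol
P_REF = 1.0e5  # Pa; reference pressure for all liquid-phase properties
ETA_MAX = 0.74  # close-packing bound on the packing fraction

# universal model constants of the second-order dispersion term
_A = np.array([
    [0.9105631445, -0.3084016918, -0.0906148351],
    [0.6361281449, 0.1860531159, 0.4527842806],
    [2.6861347891, -2.5030047259, 0.5962700728],
    [-26.547362491, 21.419793629, -1.7241829131],
    [97.759208784, -65.255885330, -4.1302112531],
    [-159.59154087, 83.318680481, 13.776631870],
    [91.297774084, -33.746922930, -8.6728470368],
])
_B = np.array([
    [0.7240946941, -0.5755498075, 0.0976883116],
    [2.2382791861, 0.6995095521, -0.2557574982],
    [-4.0025849485, 3.8925673390, -9.1558561530],
    [-21.003576815, -17.215471648, 20.642075974],
    [26.855641363, 192.67226447, -38.804430052],
    [206.55133841, -161.82646165, 93.626774077],
    [-355.60235612, -165.20769346, -29.666905585],
])

_CSTEP = 1e-30  # complex-step size


@dataclass(frozen=True)
class PcSaftParams:
    """Pure-component PC-SAFT parameter record.

    m_seg: segment number; sigma: segment diameter (angstrom); eps_k:
    dispersion energy over k_B (K); eps_assoc_k: association energy over
    k_B (K); kappa_assoc: association volume; N_assoc: total association
    site count (split equally into donors and acceptors, fractional
    allowed).
    """

    name: str
    m_seg: float
    sigma: float
    eps_k: float
    eps_assoc_k: float = 0.0
    kappa_assoc: float = 0.0
    N_assoc: float = 0.0

    def __post_init__(self) -> None:
        if not (self.m_seg > 0 and self.sigma > 0 and self.eps_k > 0):
            raise ValueError(f"{self.name}: m_seg, sigma, eps_k must be positive")
        if not (0.0 <= self.kappa_assoc < 1.0):
            raise ValueError(f"{self.name}: kappa_assoc must be in [0, 1)")
        if self.N_assoc < 0 or self.eps_assoc_k < 0:
            raise ValueError(f"{self.name}: association parameters must be >= 0")


@dataclass(frozen=True)
class KijModel:
    """Binary dispersion correction k_ij(T) = k_int + k_slope * T."""

    k_int: float = 0.0
    k_slope: float = 0.0  # 1/K

    def __call__(self, T: float) -> float:
        return self.k_int + self.k_slope * T


@dataclass
class PcSaftState:
    """A converged single-phase state with its Helmholtz decomposition."""

    T: float
    P: float
    x: np.ndarray
    eta: float
    rho: float  # number density, 1/angstrom^3
    a_hc: float
    a_disp: float
    a_assoc: float
    a_res: float
    Z: float
    ln_phi: np.ndarray


@dataclass
class LLEResult:
    """One temperature point of the amorphous-amorphous coexistence curve."""

    T: float
    x_L1: float  # API mole fraction, API-poor phase
    x_L2: float  # API mole fraction, API-rich phase
    converged: bool
    residual: float


class Mixture:
    """A PC-SAFT mixture with an optional binary dispersion correction.

    The heavy lifting lives in :meth:`a_res`, which accepts complex number
    densities and compositions so that pressure and chemical-potential
    derivatives come out of complex steps at machine precision.
    """

    def __init__(self, components: Sequence[PcSaftParams],
                 kij: KijModel | float = 0.0) -> None:
        self.components = list(components)
        self.kij = kij if isinstance(kij, KijModel) else KijModel(k_int=float(kij))
        self.m = np.array([c.m_seg for c in components])
        self.sigma = np.array([c.sigma for c in components])
        self.eps = np.array([c.eps_k for c in components])
        self.eps_ab = np.array([c.eps_assoc_k for c in components])
        self.kappa = np.array([c.kappa_assoc for c in components])
        self.nsite = np.array([c.N_assoc for c in components])
        self.sig_ij = 0.5 * (self.sigma[:, None] + self.sigma[None, :])
        # Wolbach-Sandler cross-association rules
        self.eps_ab_ij = 0.5 * (self.eps_ab[:, None] + self.eps_ab[None, :])
        self.kappa_ij = (
            np.sqrt(self.kappa[:, None] * self.kappa[None, :])
            * (np.sqrt(self.sigma[:, None] * self.sigma[None, :]) / self.sig_ij) ** 3
        )
        # a pair associates only if both carry sites and the cross energy is nonzero
        self.assoc_pair = (
            (self.kappa_ij > 0)
            & (self.eps_ab_ij > 0)
            & (self.nsite[:, None] > 0)
            & (self.nsite[None, :] > 0)
        )
        self.has_assoc = bool(np.any(self.assoc_pair))

    # -- geometry ----------------------------------------------------------
    def d(self, T: float) -> np.ndarray:
        """Temperature-dependent segment diameter, angstrom."""
        return self.sigma * (1.0 - 0.12 * np.exp(-3.0 * self.eps / T))

    def eta_to_rho(self, T: float, eta, x):
        d3 = self.d(T) ** 3
        return 6.0 * np.asarray(eta) / (math.pi * float(np.real(np.sum(np.asarray(x) * self.m * d3))))

    def rho_to_eta(self, T: float, rho, x):
        d3 = self.d(T) ** 3
        return math.pi / 6.0 * np.asarray(rho) * float(np.real(np.sum(np.asarray(x) * self.m * d3)))

    # -- Helmholtz energy --------------------------------------------------
    def a_res(self, T: float, rho, x, parts: bool = False):
        """Residual Helmholtz energy per molecule per kT.

        ``rho`` (number density, 1/angstrom^3) may be scalar or array and
        may be complex; ``x`` likewise (mole fractions; complex steps need
        not be renormalized).
        """
        rho = np.atleast_1d(np.asarray(rho))
        x = np.asarray(x)
        d = self.d(T)
        xm = x * self.m
        zeta = [math.pi / 6.0 * rho * np.sum(xm * d**n) for n in range(4)]
        z0, z1, z2, z3 = zeta
        one_m3 = 1.0 - z3
        mbar = np.sum(xm)

        # hard-sphere mixture + chain connectivity
        a_hs = (
            3.0 * z1 * z2 / one_m3
            + z2**3 / (z3 * one_m3**2)
            + (z2**3 / z3**2 - z0) * np.log(one_m3)
        ) / z0
        dii = d / 2.0  # d_i*d_i/(d_i+d_i)
        g_ii = (
            1.0 / one_m3[..., None]
            + dii * 3.0 * z2[..., None] / one_m3[..., None] ** 2
            + dii**2 * 2.0 * z2[..., None] ** 2 / one_m3[..., None] ** 3
        )
        a_hc = mbar * a_hs - np.log(g_ii) @ (x * (self.m - 1.0))

        # dispersion
        eta = z3
        mf1 = (mbar - 1.0) / mbar
        mf2 = mf1 * (mbar - 2.0) / mbar
        ai = _A[:, 0] + mf1 * _A[:, 1] + mf2 * _A[:, 2]
        bi = _B[:, 0] + mf1 * _B[:, 1] + mf2 * _B[:, 2]
        powers = eta[..., None] ** np.arange(7)
        I1 = powers @ ai
        I2 = powers @ bi
        C1 = 1.0 / (
            1.0
            + mbar * (8.0 * eta - 2.0 * eta**2) / one_m3**4
            + (1.0 - mbar)
            * (20.0 * eta - 27.0 * eta**2 + 12.0 * eta**3 - 2.0 * eta**4)
            / (one_m3 * (2.0 - eta)) ** 2
        )
        eps_ij = np.sqrt(self.eps[:, None] * self.eps[None, :]) * (1.0 - self.kij(T))
        np.fill_diagonal(eps_ij, self.eps)  # k_ij corrects cross terms only
        mm = np.outer(xm, xm)
        m2es3 = np.sum(mm * (eps_ij / T) * self.sig_ij**3)
        m2e2s3 = np.sum(mm * (eps_ij / T) ** 2 * self.sig_ij**3)
        a_disp = -2.0 * math.pi * rho * I1 * m2es3 - math.pi * rho * mbar * C1 * I2 * m2e2s3

        # association
        if self.has_assoc:
            a_assoc = self._a_assoc(T, rho, x, d, z2, z3)
        else:
            a_assoc = np.zeros_like(rho)

        if parts:
            return a_hc, a_disp, a_assoc
        return a_hc + a_disp + a_assoc

    def _a_assoc(self, T: float, rho, x, d, z2, z3):
        one_m3 = 1.0 - z3
        dmat = np.outer(d, d) / (d[:, None] + d[None, :])
        g_ij = (
            1.0 / one_m3[..., None, None]
            + dmat * 3.0 * z2[..., None, None] / one_m3[..., None, None] ** 2
            + dmat**2 * 2.0 * z2[..., None, None] ** 2 / one_m3[..., None, None] ** 3
        )
        delta = (
            g_ij
            * self.sig_ij**3
            * self.kappa_ij
            * np.expm1(self.eps_ab_ij / T)
            * self.assoc_pair
        )
        # A_ij = rho * x_j * (N_j/2) * Delta_ij
        A = rho[..., None, None] * (x * self.nsite / 2.0) * delta
        X = self._solve_site_fractions(A)
        contrib = self.nsite * (np.log(X) - X / 2.0 + 0.5)
        return contrib @ x

    @staticmethod
    def _solve_site_fractions(A, tol: float = 1e-12, maxiter: int = 80):
        """Newton solve of X_i (1 + sum_j A_ij X_j) = 1 at every grid point.

        ``A`` has shape (..., n, n); complex dtypes pass through exactly at
        convergence (complex-step differentiation).
        """
        n = A.shape[-1]
        arow = np.sum(A, axis=-1)
        safe = np.where(np.abs(arow) > 1e-14, arow, 1e-14)
        X = np.where(np.abs(arow) > 1e-14,
                     (np.sqrt(1.0 + 4.0 * safe) - 1.0) / (2.0 * safe),
                     np.ones_like(arow))
        # damped successive substitution walks into the Newton basin even
        # for very strong association (site fractions near zero)
        for _ in range(15):
            X = 0.5 * X + 0.5 / (1.0 + np.einsum("...ij,...j->...i", A, X))
        eye = np.eye(n)
        for _ in range(maxiter):
            AX = np.einsum("...ij,...j->...i", A, X)
            F = X * (1.0 + AX) - 1.0
            if np.max(np.abs(F)) < tol:
                return X
            J = eye * (1.0 + AX)[..., None] + X[..., None] * A
            step = np.linalg.solve(J, F[..., None])[..., 0]
            # backtrack to keep every site fraction strictly positive
            alpha = 1.0
            for _ in range(40):
                X_new = X - alpha * step
                if np.all(np.real(X_new) > 0):
                    break
                alpha *= 0.5
            X = X_new
        # globally convergent fallback: heavily damped successive substitution
        for _ in range(20000):
            X_new = 0.7 * X + 0.3 / (1.0 + np.einsum("...ij,...j->...i", A, X))
            if np.max(np.abs(X_new - X)) < 0.1 * tol:
                return X_new
            X = X_new
        raise RuntimeError("association site fractions did not converge")

    # -- derived properties -------------------------------------------------
    def compressibility(self, T: float, rho, x):
        """Z = 1 + rho * d(a_res)/d(rho), derivative by complex step."""
        rho = np.atleast_1d(np.asarray(rho, dtype=float))
        a = self.a_res(T, rho + 1j * _CSTEP, x)
        return 1.0 + rho * np.imag(a) / _CSTEP

    def pressure(self, T: float, rho, x):
        """Pressure (Pa) at number density rho (1/angstrom^3)."""
        Z = self.compressibility(T, rho, x)
        return Z * np.asarray(rho) * 1e30 * KB * T

    def density(self, T: float, P: float, x, phase: str = "liquid",
                rho_guess: float | None = None, n_scan: int = 160) -> float:
        """Density root of P(eta) = P; returns number density (1/angstrom^3).

        The liquid root is the largest packing-fraction root in
        (0, ETA_MAX), found by a deterministic descending scan and refined
        with Brent's method.  A ``rho_guess`` (e.g. from a neighboring
        state) short-circuits the scan with a local bracket.
        """
        if P <= 0:
            raise ValueError("P must be positive")
        x = np.asarray(x, dtype=float)

        def f_eta(eta):
            return float(self.pressure(T, self.eta_to_rho(T, eta, x), x)[0]) - P

        if rho_guess is not None:
            eta0 = float(self.rho_to_eta(T, rho_guess, x))
            if not (1e-6 < eta0 < 0.70):
                rho_guess = None  # stale guess (e.g. composition jump)
        if rho_guess is not None:
            lo, hi = 0.95 * eta0, min(1.05 * eta0, ETA_MAX)
            flo, fhi = f_eta(lo), f_eta(hi)
            for _ in range(6):
                if flo * fhi <= 0:
                    eta = optimize.brentq(f_eta, lo, hi, xtol=1e-14, rtol=1e-15)
                    return float(self.eta_to_rho(T, eta, x))
                lo, hi = max(0.8 * lo, 1e-12), min(1.2 * hi, ETA_MAX)
                flo, fhi = f_eta(lo), f_eta(hi)
            # guess failed; fall back to the full scan

        etas = np.linspace(ETA_MAX, 1e-10, n_scan)
        f = self.pressure(T, self.eta_to_rho(T, etas, x), x) - P
        sign = np.sign(f)
        idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
        if idx.size == 0:
            raise RuntimeError(
                f"no density root at T={T:g} K, P={P:g} Pa within eta (0, {ETA_MAX})"
            )
        k = idx[0] if phase == "liquid" else idx[-1]
        eta = optimize.brentq(f_eta, etas[k + 1], etas[k], xtol=1e-14, rtol=1e-15)
        return float(self.eta_to_rho(T, eta, x))

    def ln_phi(self, T: float, P: float, x, rho: float | None = None) -> np.ndarray:
        """Fugacity coefficients ln(phi_i) of the liquid at (T, P, x).

        ln(phi_i) = mu_i_res/kT - ln Z with
        mu_i_res/kT = a + (Z-1) + da/dx_i - sum_j x_j da/dx_j, the
        composition derivatives taken at constant total number density.
        """
        x = np.asarray(x, dtype=float)
        if rho is None:
            rho = self.density(T, P, x)
        a = float(np.real(self.a_res(T, rho, x)[0]))
        Z = float(self.compressibility(T, rho, x)[0])
        dadx = np.empty(x.size)
        for i in range(x.size):
            xc = x.astype(complex)
            xc[i] += 1j * _CSTEP
            dadx[i] = np.imag(self.a_res(T, rho, xc)[0]) / _CSTEP
        mu_res = a + (Z - 1.0) + dadx - float(x @ dadx)
        return mu_res - np.log(Z)

    def state(self, T: float, P: float, x) -> PcSaftState:
        """Converged liquid state with the full Helmholtz decomposition."""
        x = np.asarray(x, dtype=float)
        rho = self.density(T, P, x)
        hc, disp, assoc = (float(np.real(np.atleast_1d(v)[0]))
                           for v in self.a_res(T, rho, x, parts=True))
        Z = float(self.compressibility(T, rho, x)[0])
        return PcSaftState(
            T=T, P=P, x=x, eta=float(self.rho_to_eta(T, rho, x)), rho=rho,
            a_hc=hc, a_disp=disp, a_assoc=assoc, a_res=hc + disp + assoc,
            Z=Z, ln_phi=self.ln_phi(T, P, x, rho=rho),
        )


class _GammaTracker:
    """Warm-started activity-coefficient evaluator for one binary mixture.

    Root-finding loops (SLE, LLE, k_ij fitting) call the EOS at nearby
    states; reusing the previous density roots as local brackets avoids a
    full packing-fraction scan on every call.
    """

    def __init__(self, mix: Mixture, P: float = P_REF) -> None:
        self.mix = mix
        self.pures = [Mixture([c]) for c in mix.components]
        self.P = P
        self._rho_mix: float | None = None
        self._rho_pure: list[float | None] = [None] * len(mix.components)

    def ln_gammas(self, T: float, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        try:
            rho = self.mix.density(T, self.P, x, rho_guess=self._rho_mix)
        except RuntimeError:
            rho = self.mix.density(T, self.P, x)
        self._rho_mix = rho
        ln_mix = self.mix.ln_phi(T, self.P, x, rho=rho)
        out = np.empty_like(ln_mix)
        one = np.array([1.0])
        for i, pure in enumerate(self.pures):
            if x[i] == 1.0:
                out[i] = 0.0  # normalization gamma_i(pure i) = 1 is exact
                continue
            rp = pure.density(T, self.P, one, rho_guess=self._rho_pure[i])
            self._rho_pure[i] = rp
            out[i] = ln_mix[i] - float(pure.ln_phi(T, self.P, one, rho=rp)[0])
        return out

    def gammas(self, T: float, x) -> np.ndarray:
        return np.exp(self.ln_gammas(T, x))

    def ln_gamma_api(self, T: float, x_api: float) -> float:
        return float(self.ln_gammas(T, np.array([x_api, 1.0 - x_api]))[0])


def activity_coefficients(mix: Mixture, T: float, P: float = P_REF,
                          x=None) -> np.ndarray:
    """gamma_i = phi_i(mixture) / phi_i(pure i) at the same (T, P)."""
    return _GammaTracker(mix, P).gammas(T, np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# solid-liquid equilibrium


def ideal_solubility(api: CompoundThermo, T: float) -> float:
    """Mole-fraction solubility of the crystalline drug at unit activity.

    exp[-dHfus/(RT)(1 - T/Tm) - dCp/R (1 - Tm/T + ln(Tm/T))]; equals 1 at
    T = Tm.
    """
    if api.Tm is None or api.dHfus is None:
        raise ValueError(f"{api.name}: needs Tm and dHfus")
    dCp = api.dCp or 0.0
    arg = (
        -api.dHfus / (R * T) * (1.0 - T / api.Tm)
        - dCp / R * (1.0 - api.Tm / T + math.log(api.Tm / T))
    )
    return math.exp(arg)


def sle_solubility(mix: Mixture, api: CompoundThermo, T: float,
                   P: float = P_REF, method: str = "fixed_point",
                   tol: float = 1e-10, max_iter: int = 200,
                   damping: float = 0.5) -> tuple[float, float]:
    """Drug mole-fraction solubility in the polymer melt at temperature T.

    Returns ``(x_API, x_ideal)``; the API must be component 0 of ``mix``.
    ``method='fixed_point'`` damps x <- (1-d) x + d K/gamma(x) (bisection
    fallback on stall); ``method='bisection'`` scans f(x) = x gamma(x) - K
    on a log grid and refines the smallest bracket (the stable-solution
    branch) -- the independent oracle route.
    """
    if T > api.Tm:
        raise ValueError(f"T={T:g} K exceeds Tm={api.Tm:g} K")
    K = ideal_solubility(api, T)
    if T == api.Tm:
        return 1.0, 1.0
    lnK = math.log(K)
    tracker = _GammaTracker(mix, P)

    def f(x):
        # log-space isotherm residual; f(x->1) = -lnK > 0, f(x->0) -> -inf
        return math.log(x) + tracker.ln_gamma_api(T, x) - lnK

    if method == "fixed_point":
        u = math.log(min(K, 0.999999))
        for _ in range(max_iter):
            u_new = lnK - tracker.ln_gamma_api(T, min(math.exp(u), 0.999999))
            u_new = min(max(u_new, math.log(1e-12)), math.log(0.999999))
            u_next = (1.0 - damping) * u + damping * u_new
            if abs(u_next - u) < tol:
                return _refine_root(f, math.exp(u_next)), K
            u = u_next
        method = "bisection"  # stalled: fall back
    if method != "bisection":
        raise ValueError("method must be 'fixed_point' or 'bisection'")
    grid = np.logspace(-8, 0, 120)
    grid[-1] = 0.999999
    vals = np.array([f(g) for g in grid])
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if idx.size == 0:
        raise RuntimeError(f"SLE has no root at T={T:g} K (x_ideal={K:.3g})")
    k = idx[0]  # smallest root: the stable-solution branch
    x = optimize.brentq(f, grid[k], grid[k + 1], xtol=1e-14, rtol=1e-14)
    return float(x), K


def _refine_root(f, x0: float, rel: float = 1e-6) -> float:
    lo, hi = x0 * (1.0 - 50 * rel), min(x0 * (1.0 + 50 * rel), 0.9999999)
    flo, fhi = f(lo), f(hi)
    if flo * fhi <= 0:
        return float(optimize.brentq(f, lo, hi, xtol=1e-14, rtol=1e-14))
    return float(x0)


def sle_temperature(mix: Mixture, api: CompoundThermo, x_api: float,
                    P: float = P_REF, t_lo: float = 250.0,
                    tracker: _GammaTracker | None = None) -> float:
    """Saturation temperature at drug mole fraction ``x_api``.

    Solves ln(x gamma(x, T)) = ln(x_ideal(T)) for T directly (no inner
    composition solve); this is the quantity melting-point-depression data
    report.
    """
    if not (0.0 < x_api <= 1.0):
        raise ValueError("x_api must be in (0, 1]")
    if x_api == 1.0:
        return api.Tm
    tr = tracker if tracker is not None else _GammaTracker(mix, P)

    def h(T):
        return (math.log(x_api) + tr.ln_gamma_api(T, x_api)
                - math.log(ideal_solubility(api, T)))

    hi = api.Tm - 1e-9
    lo = t_lo
    h_hi = h(hi)
    if h_hi >= 0.0:
        # drug activity exceeds the crystal's even at the melting point:
        # the gross composition sits inside a demixing (LLE) region whose
        # drug-rich phase is essentially pure, so the observable melting
        # end-set plateaus at Tm
        return api.Tm
    if h(lo) * h_hi > 0:
        raise RuntimeError(f"no saturation-temperature bracket for x={x_api:g} "
                           f"in ({lo:g}, {hi:g}) K")
    return float(optimize.brentq(h, lo, hi, xtol=1e-7, rtol=1e-12))


# ---------------------------------------------------------------------------
# liquid-liquid equilibrium


def _gmix(tracker: _GammaTracker, T: float, x1) -> np.ndarray:
    """Dimensionless molar Gibbs energy of mixing on a composition grid."""
    x1 = np.atleast_1d(np.asarray(x1, dtype=float))
    out = np.empty_like(x1)
    for i, xi in enumerate(x1):
        lg = tracker.ln_gammas(T, np.array([xi, 1.0 - xi]))
        out[i] = (xi * (math.log(xi) + lg[0])
                  + (1.0 - xi) * (math.log(1.0 - xi) + lg[1]))
    return out


def spinodal_window(mix: Mixture, T: float, P: float = P_REF,
                    n: int = 31) -> tuple[float, float] | None:
    """Concave window of g_mix(x1) (finite-difference d2g/dx2 < 0), or None.

    This is the spinodal region on a coarse composition grid; it seeds and
    sanity-checks the binodal solve.
    """
    tracker = _GammaTracker(mix, P)
    u = np.linspace(-6, math.log10(0.5), n)
    x = np.unique(np.concatenate([10.0**u, 1.0 - 10.0**u]))
    x.sort()
    g = _gmix(tracker, T, x)
    h1 = np.diff(x)
    d2 = 2.0 * (g[:-2] * h1[1:] - g[1:-1] * (h1[:-1] + h1[1:]) + g[2:] * h1[:-1]) / (
        h1[:-1] * h1[1:] * (h1[:-1] + h1[1:])
    )
    neg = np.nonzero(d2 < 0)[0]
    if neg.size == 0:
        return None
    return float(x[neg[0]]), float(x[neg[-1] + 2])


def lle_point(mix: Mixture, T: float, P: float = P_REF,
              guess: tuple[float, float] | None = None) -> LLEResult:
    """Solve the two isoactivity equations at one temperature.

    Unknowns are (ln x1_L1, ln x2_L2), keeping both phases inside the
    composition simplex; the trivial root x_L1 == x_L2 is rejected.
    """
    guesses: list[tuple[float, float]] = []
    if guess is not None:
        guesses.append(guess)
    window = spinodal_window(mix, T, P)
    if window is not None:
        lo, hi = window
        c = 0.5 * (lo + hi)
        # straddle the concave window by reflecting its edges outward; the
        # dome can sit anywhere on the composition axis (for polymeric
        # mixtures often crammed against x -> 1)
        for f in (1.5, 3.0, 8.0):
            guesses.append((min(max(c - f * (c - lo), 1e-10), 1.0 - 1e-12),
                            min(max(c + f * (hi - c), 1e-10), 1.0 - 1e-12)))
    if not guesses:
        return LLEResult(T=T, x_L1=math.nan, x_L2=math.nan,
                         converged=False, residual=math.inf)
    tracker = _GammaTracker(mix, P)

    def split(u):
        # logit coordinates resolve phases pinned against either pure axis
        u = min(max(u, -690.0), 690.0)
        return 1.0 / (1.0 + math.exp(-u)), 1.0 / (1.0 + math.exp(u))

    def lnact(x1, x2):
        lg = tracker.ln_gammas(T, np.array([x1, x2]))
        return math.log(x1) + lg[0], math.log(x2) + lg[1]

    def eqs(u):
        la = lnact(*split(u[0]))
        lb = lnact(*split(u[1]))
        return [la[0] - lb[0], la[1] - lb[1]]

    def logit(x):
        x = min(max(x, 1e-14), 1.0 - 1e-14)
        return math.log(x / (1.0 - x))

    best: LLEResult | None = None
    r = None
    for a0, b0 in guesses:
        sol = optimize.root(eqs, [logit(a0), logit(b0)],
                            method="hybr", options={"xtol": 1e-12})
        a = split(sol.x[0])[0]
        b = split(sol.x[1])[0]
        res = float(np.max(np.abs(eqs(sol.x))))
        ok = res < 1e-8 and abs(b - a) > 1e-6
        r = LLEResult(T=T, x_L1=min(a, b), x_L2=max(a, b), converged=ok,
                      residual=res)
        if ok and (best is None or res < best.residual):
            best = r
        if best is not None and best.residual < 1e-10:
            break
    if best is None:
        best = r  # last attempt, flagged unconverged
    return best


def lle_curve(mix: Mixture, T_grid, P: float = P_REF) -> list[LLEResult]:
    """Isoactivity binodal over a temperature grid, with continuation.

    Non-convergence at a single grid temperature is recorded on that
    result, not fatal.
    """
    out: list[LLEResult] = []
    guess = None
    for T in np.asarray(T_grid, dtype=float):
        r = lle_point(mix, float(T), P, guess=guess)
        out.append(r)
        if r.converged:
            guess = (r.x_L1, r.x_L2)
    return out


# ---------------------------------------------------------------------------
# k_ij fitting


def fit_kij(ds: MPDDataset, api_pars: PcSaftParams, poly_pars: PcSaftParams,
            api: CompoundThermo, poly: CompoundThermo,
            mode: str = "constant", bounds: tuple[float, float] = (-0.05, 0.15),
            coarse_step: float = 0.005, fine_step: float = 0.001,
            cache: dict | None = None) -> tuple[KijModel, FitReport]:
    """Fit the binary correction to melting-point-depression data.

    Minimizes the AARD between observed end-set temperatures and the
    model's saturation temperature at each composition with a
    deterministic coarse grid (``coarse_step``) followed by a local fine
    grid (``fine_step``) around the coarse optimum.  ``mode='linear'``
    adds a temperature slope refined by Nelder-Mead from the constant-k
    optimum.

    ``cache`` maps kij -> predicted temperature array; it may be shared
    across calls whose datasets use the same composition design (noise
    replicates of one experiment), where the model curve is identical.
    """
    w, T_obs = ds.active()
    x_obs = np.array([convert_composition(wi, "w", "x", api, poly) for wi in w])
    if cache is None:
        cache = {}

    t_floor = 150.0  # saturation below this is clamped (penalizes that k_ij)

    def predict(kij: float) -> np.ndarray:
        key = round(float(kij), 6)
        if key not in cache:
            mix = Mixture([api_pars, poly_pars], kij=KijModel(k_int=key))
            tr = _GammaTracker(mix)
            pred = np.empty_like(x_obs)
            for i, xi in enumerate(x_obs):
                try:
                    pred[i] = sle_temperature(mix, api, xi, tracker=tr,
                                              t_lo=t_floor)
                except RuntimeError:
                    pred[i] = t_floor
            cache[key] = pred
        return cache[key]

    def objective(kij: float) -> float:
        pred = predict(kij)
        return float(100.0 * np.mean(np.abs(T_obs - pred) / T_obs))

    lo, hi = bounds
    coarse = np.arange(lo, hi + 0.5 * coarse_step, coarse_step)
    vals = np.array([objective(k) for k in coarse])
    if float(np.ptp(vals)) < 1e-10:
        warnings.warn("k_ij objective is flat over the search range")
    k_best = float(coarse[int(np.argmin(vals))])
    fine = np.arange(k_best - coarse_step, k_best + coarse_step + 0.5 * fine_step,
                     fine_step)
    fine = fine[(fine >= lo) & (fine <= hi)]
    fvals = np.array([objective(k) for k in fine])
    k_best = float(fine[int(np.argmin(fvals))])
    model = KijModel(k_int=k_best)
    pred = predict(k_best)

    if mode == "linear":
        def obj2(p):
            mix = Mixture([api_pars, poly_pars],
                          kij=KijModel(k_int=float(p[0]), k_slope=float(p[1])))
            tr = _GammaTracker(mix)
            pr = np.array([sle_temperature(mix, api, xi, tracker=tr) for xi in x_obs])
            return float(100.0 * np.mean(np.abs(T_obs - pr) / T_obs))

        res = optimize.minimize(obj2, [k_best, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-8,
                                         "maxiter": 120})
        model = KijModel(k_int=float(res.x[0]), k_slope=float(res.x[1]))
        tr = _GammaTracker(Mixture([api_pars, poly_pars], kij=model))
        pred = np.array([sle_temperature(tr.mix, api, xi, tracker=tr)
                         for xi in x_obs])
    elif mode != "constant":
        raise ValueError("mode must be 'constant' or 'linear'")

    report = FitReport.from_predictions(
        f"pcsaft_kij_{mode}",
        {"k_int": model.k_int, "k_slope": model.k_slope},
        T_obs, pred,
    )
    return model, report


# ---------------------------------------------------------------------------
# I/O


def load_pcsaft_params(path: str | Path | None = None) -> dict[str, PcSaftParams]:
    """Read a PC-SAFT parameter registry (bundled table if no path given)."""
    if path is None:
        path = Path(resources.files("asdkit").joinpath("data", "pcsaft.json"))
    raw = json.loads(Path(path).read_text())
    out: dict[str, PcSaftParams] = {}
    for i, rec in enumerate(raw):
        try:
            p = PcSaftParams(**rec)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"pcsaft record {i}: {exc}") from exc
        if p.name in out:
            raise ValueError(f"duplicate component {p.name!r}")
        out[p.name] = p
    return out
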