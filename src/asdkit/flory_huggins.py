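"""Flory-Huggins melting-point-depression analysis and phase boundaries.

The lattice model treats the drug as the reference site and the polymer as
a chain of ``m`` sites, with ``m`` the molar-volume ratio
``(Mw_p/rho_p)/(Mw_a/rho_a)``.  Solid-liquid equilibrium of the
crystalline drug in the melt obeys

    1/T - 1/Tm = -(R/dHfus) [ln(phi) + (1 - 1/m)(1 - phi) + chi (1 - phi)^2]

with ``phi`` the drug volume fraction and the interaction parameter
modeled as ``chi(T) = A + B/T`` (UCST behavior when A < 0, B > 0).  The
dimensionless mixing free energy per lattice site is

    g(phi) = phi ln(phi) + ((1 - phi)/m) ln(1 - phi) + chi phi (1 - phi)

whose common tangent gives the binodal and whose inflection points
(1/phi + 1/(m (1-phi)) = 2 chi) give the spinodal.  The critical point has
the closed forms phi_c = 1/(1 + sqrt(m)), chi_c = (1 + 1/sqrt(m))^2 / 2,
used as an independent check on the numeric solvers.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .core import R, CompoundThermo, MPDDataset, convert_composition

__all__ = [
    "FHModel",
    "ChiPoint",
    "GibbsCurve",
    "volume_ratio",
    "chi_per_point",
    "chi_points",
    "chi_slope_fit",
    "chi_temperature_fit",
    "sle_curve",
    "sle_temperature",
    "gibbs_curve",
    "spinodal_phis",
    "spinodal_curve",
    "critical_point",
    "binodal",
    "binodal_gridsearch",
]


def volume_ratio(api: CompoundThermo, poly: CompoundThermo) -> float:
    """Polymer-to-drug molar volume ratio m = (Mw_p/rho_p)/(Mw_a/rho_a)."""
    return poly.molar_volume / api.molar_volume


@dataclass(frozen=True)
class FHModel:
    """A parameterized Flory-Huggins description of one drug-polymer pair."""

    api: CompoundThermo
    poly: CompoundThermo
    A: float
    B: float  # K

    @property
    def m(self) -> float:
        return volume_ratio(self.api, self.poly)

    def chi(self, T):
        """chi(T) = A + B/T."""
        T = np.asarray(T, dtype=float)
        out = self.A + self.B / T
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ChiPoint:
    w_API: float
    phi_poly: float
    T_end: float  # K
    chi: float


@dataclass(frozen=True)
class GibbsCurve:
    T: float
    grid: np.ndarray  # phi_API, strictly increasing in (0, 1)
    g: np.ndarray  # Delta_mix G / (RT) per lattice site


# ---------------------------------------------------------------------------
# chi extraction from MPD data


def _depression_lhs(T, Tm, dHfus):
    """(-dHfus/R) (1/T - 1/Tm); zero at T = Tm, positive below."""
    return (-dHfus / R) * (1.0 / T - 1.0 / Tm)


def chi_per_point(w: float, T_end: float, api: CompoundThermo,
                  poly: CompoundThermo) -> ChiPoint:
    """Invert the SLE relation for chi at one (composition, end-set T) point."""
    if not (0.0 < w < 1.0):
        raise ValueError("w must be strictly inside (0, 1)")
    m = volume_ratio(api, poly)
    phi = convert_composition(w, "w", "phi", api, poly)
    phi_p = 1.0 - phi
    chi = (
        _depression_lhs(T_end, api.Tm, api.dHfus)
        - np.log(phi)
        - (1.0 - 1.0 / m) * phi_p
    ) / phi_p**2
    return ChiPoint(w_API=w, phi_poly=phi_p, T_end=T_end, chi=float(chi))


def chi_points(ds: MPDDataset, api: CompoundThermo,
               poly: CompoundThermo) -> list[ChiPoint]:
    """Per-point chi for every non-excluded observation with w < 1."""
    w, T = ds.active()
    return [chi_per_point(wi, Ti, api, poly) for wi, Ti in zip(w, T) if wi < 1.0]


def chi_slope_fit(ds: MPDDataset, api: CompoundThermo,
                  poly: CompoundThermo) -> tuple[float, float]:
    """Single chi from the through-origin slope of the linearized SLE relation.

    Regresses Y = (-dHfus/R)(1/T - 1/Tm) - ln(phi) - (1 - 1/m) phi_p
    against phi_p^2 with zero intercept; returns (chi, r^2 of the
    through-origin regression).
    """
    w, T = ds.active()
    if np.ptp(w) == 0:
        raise ValueError("degenerate design: all points at the same composition")
    m = volume_ratio(api, poly)
    phi = np.array([convert_composition(wi, "w", "phi", api, poly) for wi in w])
    phi_p = 1.0 - phi
    Y = _depression_lhs(T, api.Tm, api.dHfus) - np.log(phi) - (1.0 - 1.0 / m) * phi_p
    X = phi_p**2
    slope = float(np.dot(X, Y) / np.dot(X, X))
    ss_res = float(np.sum((Y - slope * X) ** 2))
    ss_tot = float(np.sum(Y**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, r2


def chi_temperature_fit(points: Sequence[ChiPoint]) -> tuple[float, float]:
    """Ordinary least squares of chi on 1/T; returns (A intercept, B slope K).

    A < 0 with B > 0 indicates UCST behavior (demixing on cooling).
    """
    T = np.array([p.T_end for p in points], dtype=float)
    chi = np.array([p.chi for p in points], dtype=float)
    if len(points) < 2 or np.ptp(T) == 0:
        raise ValueError("need at least two chi points at distinct temperatures")
    design = np.column_stack([np.ones_like(T), 1.0 / T])
    coef, *_ = np.linalg.lstsq(design, chi, rcond=None)
    return float(coef[0]), float(coef[1])


def fit_fh(ds: MPDDataset, api: CompoundThermo, poly: CompoundThermo) -> FHModel:
    """MPD dataset -> FHModel via per-point chi and the chi(T) = A + B/T fit."""
    A, B = chi_temperature_fit(chi_points(ds, api, poly))
    return FHModel(api=api, poly=poly, A=A, B=B)


# ---------------------------------------------------------------------------
# SLE curve


def sle_temperature(model: FHModel, phi: float, t_lo: float = 100.0,
                    method: str = "exact") -> float:
    """Solubility temperature at drug volume fraction ``phi``.

    With chi(T) = A + B/T the SLE relation is *linear* in 1/T, so the
    self-consistent solution has the closed form

        1/T = [1/Tm - (R/dHfus)(ln(phi) + (1-1/m)phi_p + A phi_p^2)]
              / [1 + (R/dHfus) B phi_p^2].

    ``method='bracket'`` solves the same equation by deterministic Brent
    root finding instead (the validation route).  A result slightly above
    Tm is legitimate: it flags compositions whose melt activity exceeds
    the crystal's (an incipient-demixing signature), where the observable
    end-set plateaus at Tm.
    """
    api = model.api
    if phi == 1.0:
        return api.Tm
    if not (0.0 < phi < 1.0):
        raise ValueError("phi must be in (0, 1]")
    m = model.m
    phi_p = 1.0 - phi
    RdH = R / api.dHfus

    if method == "exact":
        base = np.log(phi) + (1.0 - 1.0 / m) * phi_p + model.A * phi_p**2
        u = (1.0 / api.Tm - RdH * base) / (1.0 + RdH * model.B * phi_p**2)
        if not (np.isfinite(u) and u > 0):
            raise ValueError(f"no physical SLE solution at phi={phi:g}")
        T = float(1.0 / u)
        if T < t_lo:
            raise ValueError(f"SLE temperature {T:.1f} K below t_lo={t_lo:g} K "
                             f"at phi={phi:g}")
        return T
    if method != "bracket":
        raise ValueError("method must be 'exact' or 'bracket'")

    def h(T):
        mix = np.log(phi) + (1.0 - 1.0 / m) * phi_p + model.chi(T) * phi_p**2
        return 1.0 / T - 1.0 / api.Tm + RdH * mix

    hi = api.Tm + 50.0
    if h(t_lo) * h(hi) > 0:
        raise ValueError(
            f"no SLE root for phi={phi:g} in ({t_lo:g}, {hi:g}) K "
            f"(h({t_lo:g})={h(t_lo):.3g}, h({hi:g})={h(hi):.3g})"
        )
    return float(optimize.brentq(h, t_lo, hi, xtol=1e-10, rtol=1e-12))


def sle_curve(model: FHModel, grid, basis: str = "phi") -> np.ndarray:
    """Solubility temperatures over a composition grid.

    Returns an array of shape (n, 2): (composition on the input basis, T K).
    """
    grid = np.asarray(grid, dtype=float)
    out = np.empty((grid.size, 2))
    for i, c in enumerate(grid):
        phi = convert_composition(float(c), basis, "phi", model.api, model.poly)
        out[i] = (c, sle_temperature(model, phi))
    return out


# ---------------------------------------------------------------------------
# mixing free energy and phase boundaries


def _g_of_phi(phi, m, chi):
    phi = np.asarray(phi, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(phi > 0, phi * np.log(np.where(phi > 0, phi, 1.0)), 0.0)
        termp = np.where(
            phi < 1, ((1 - phi) / m) * np.log(np.where(phi < 1, 1 - phi, 1.0)), 0.0
        )
        return term + termp + chi * phi * (1 - phi)


def _dg_dphi(phi, m, chi):
    with np.errstate(divide="ignore", invalid="ignore"):
        return (np.log(phi) + 1.0 - (np.log(1.0 - phi) + 1.0) / m
                + chi * (1.0 - 2.0 * phi))


def gibbs_curve(model: FHModel, T: float, grid=None) -> GibbsCurve:
    """Dimensionless mixing free energy g(phi) at temperature T.

    Grid points at exactly 0 or 1 take the pure-component limit value 0.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 501)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    return GibbsCurve(T=T, grid=grid, g=_g_of_phi(grid, model.m, model.chi(T)))


def spinodal_phis(m: float, chi: float) -> tuple[float, float] | None:
    """Both spinodal compositions at a given chi, or None above the critical point.

    Roots of 2 chi m phi^2 - (2 chi m + m - 1) phi + m = 0 (the quadratic
    form of 1/phi + 1/(m(1-phi)) = 2 chi).
    """
    if chi <= 0:
        return None
    a = 2.0 * chi * m
    b = -(2.0 * chi * m + m - 1.0)
    c = m
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return None
    sq = np.sqrt(disc)
    lo = (-b - sq) / (2 * a)
    hi = (-b + sq) / (2 * a)
    if not (0 < lo <= hi < 1):
        return None
    return float(lo), float(hi)


def critical_point(m: float) -> tuple[float, float]:
    """(phi_c, chi_c) located numerically from the spinodal discriminant.

    ``phi_c`` is the *drug* volume fraction at the critical point,
    sqrt(m)/(1+sqrt(m)) in closed form -- equivalently a critical polymer
    fraction of 1/(1+sqrt(m)) -- and chi_c = (1+1/sqrt(m))^2/2.  The
    closed forms serve as the independent test oracle; this routine only
    solves disc(chi) = 0 numerically.
    """

    def disc(chi):
        b = 2.0 * chi * m + m - 1.0
        return b * b - 8.0 * chi * m * m

    # disc is convex in chi with two nonnegative zeros; the critical chi is
    # the larger one, bracketed between the vertex and a generous upper bound
    vertex = float(optimize.minimize_scalar(
        disc, bounds=(1e-12, 1e3), method="bounded",
        options={"xatol": 1e-12}).x)
    chi_c = float(optimize.brentq(disc, vertex, 1e6, xtol=1e-14, rtol=1e-15))
    phi_c = (2.0 * chi_c * m + m - 1.0) / (4.0 * chi_c * m)
    return float(phi_c), chi_c


def spinodal_curve(model: FHModel, T_grid) -> list[tuple[float, float, float]]:
    """(T, phi_lo, phi_hi) at each grid temperature where a spinodal exists."""
    out = []
    for T in np.asarray(T_grid, dtype=float):
        roots = spinodal_phis(model.m, model.chi(T))
        if roots is not None:
            out.append((float(T), roots[0], roots[1]))
    return out


def binodal(model: FHModel, T: float, method: str = "tangent") -> tuple[float, float]:
    """Coexisting compositions (phi_a, phi_b) at temperature T.

    ``method='tangent'`` (default) solves the common-tangent conditions
    g'(a) = g'(b) and g(b) - g(a) = g'(a) (b - a) by two-variable root
    finding with spinodal-bracketed starting values.  ``method='derivative'``
    instead returns the two zeros of g'(phi) (the printed first-derivative
    condition), which locates the extrema of g rather than the coexistence
    compositions; it is kept for comparison only.
    """
    m = model.m
    chi = model.chi(T)
    sp = spinodal_phis(m, chi)
    if sp is None:
        raise ValueError(f"T={T:g} K is at or above the critical point; no binodal")
    s_lo, s_hi = sp

    if method == "derivative":
        try:
            a = optimize.brentq(lambda p: _dg_dphi(p, m, chi), 1e-12, s_lo,
                                xtol=1e-14)
            b = optimize.brentq(lambda p: _dg_dphi(p, m, chi), s_hi,
                                1.0 - 1e-12, xtol=1e-14)
        except ValueError as exc:
            raise RuntimeError(
                "first-derivative-zero mode needs interior extrema of g, "
                "which this (m, chi) does not have; use method='tangent'"
            ) from exc
        return float(a), float(b)
    if method != "tangent":
        raise ValueError("method must be 'tangent' or 'derivative'")

    # unknowns u = (log phi_a, log(1 - phi_b)) keep both branches in (0,1);
    # the drug-rich branch is evaluated in eps = 1 - phi_b via log1p so a
    # phase pure to within machine epsilon still yields accurate residuals
    def eqs(u):
        a = np.exp(u[0])
        eps = min(np.exp(u[1]), 1.0 - 1e-12)
        ga, da = _g_of_phi(a, m, chi), _dg_dphi(a, m, chi)
        ln_b = np.log1p(-eps)
        ln_eps = np.log(eps)
        db = ln_b + 1.0 - (ln_eps + 1.0) / m + chi * (2.0 * eps - 1.0)
        gb = (1.0 - eps) * ln_b + (eps / m) * ln_eps + chi * (1.0 - eps) * eps
        return [da - db, (gb - ga) - da * ((1.0 - eps) - a)]

    # seed from a coarse common-tangent hull, then polish on the exact
    # tangency conditions; asymmetric m makes naive starts collapse onto
    # the trivial root a == b.  Near the critical point the coarse hull is
    # degenerate, so spinodal-reflected starts are tried as fallbacks.
    phi_c = (s_lo + s_hi) / 2.0
    seeds = []
    a0, b0 = binodal_gridsearch(m, chi, n=4001)
    seeds.append((min(a0, 0.9 * s_lo), max(b0, s_hi + 0.1 * (1.0 - s_hi))))
    for f in (1.5, 2.0, 3.0):
        seeds.append((max(phi_c - f * (phi_c - s_lo), 1e-8 * s_lo),
                      min(phi_c + f * (s_hi - phi_c), 1.0 - 1e-12)))
    best = None
    for a0, b0 in seeds:
        sol = optimize.root(eqs, [np.log(a0), np.log(1.0 - b0)], method="hybr",
                            options={"xtol": 1e-13})
        a = float(np.exp(sol.x[0]))
        b = float(1.0 - np.exp(sol.x[1]))
        res = float(np.max(np.abs(eqs(sol.x))))
        # acceptance on residual + bracket placement (hybr can flag "slow
        # progress" on an already-converged solve); b may round to 1.0 when
        # the drug-rich phase is pure to within eps, where g' saturates and
        # the attainable residual degrades
        res_tol = 1e-8 if b < 1.0 - 1e-10 else 1e-6
        ok = (res <= res_tol and 0 < a < s_lo + 1e-12
              and s_hi - 1e-12 < b <= 1.0)
        if ok and (best is None or res < best[2]):
            best = (a, b, res)
        if best is not None and best[2] < 1e-10:
            break
    if best is None:
        raise RuntimeError(
            f"binodal did not converge at T={T:g} K from any start "
            f"(spinodal brackets ({s_lo:.4g}, {s_hi:.4g}))"
        )
    return best[0], best[1]


def binodal_gridsearch(m: float, chi: float, n: int = 100001) -> tuple[float, float]:
    """Brute-force common tangent via the lower convex hull of g on a fine grid.

    Independent oracle for :func:`binodal`: the coexistence compositions
    are the endpoints of the hull segment spanning the concave window.
    """
    phi = np.linspace(0.0, 1.0, n)[1:-1]
    g = _g_of_phi(phi, m, chi)
    # Andrew's monotone-chain lower hull on (phi, g)
    hull: list[int] = []
    for i in range(phi.size):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            cross = (phi[i2] - phi[i1]) * (g[i] - g[i1]) - (g[i2] - g[i1]) * (phi[i] - phi[i1])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    hull_arr = np.asarray(hull)
    gaps = np.diff(phi[hull_arr])
    k = int(np.argmax(gaps))
    return float(phi[hull_arr[k]]), float(phi[hull_arr[k + 1]])
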