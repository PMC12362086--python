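"""Temperature-composition phase diagrams for drug-polymer blends.

Collects solubility (SLE) curves from any of the fitted models
(Flory-Huggins, Kyeremateng, PC-SAFT), amorphous-amorphous (LLE)
binodal/spinodal domes where the engine provides them, and a blend-Tg
curve, onto one canvas whose composition axis is drug load in % w/w
(the basis formulation scientists plot); volume- and mole-fraction
results are converted at the boundary.

Region semantics at a point (w, T), classified against one model's
curves with UCST-type demixing:

* ``stable solution``   -- below the solubility limit, outside any LLE dome;
* ``supersaturated``    -- above the solubility limit (metastable against
                           crystallization), outside the LLE dome;
* ``LLE metastable``    -- between binodal and spinodal (phase separation
                           favored but nucleation-limited);
* ``LLE unstable``      -- inside the spinodal (spontaneous demixing);
* a ``glassy`` qualifier is appended whenever T < Tg(w).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CompoundThermo, convert_composition
from .flory_huggins import (
    FHModel,
    binodal as fh_binodal,
    critical_point,
    sle_temperature as fh_sle_temperature,
    spinodal_phis,
)
from .kyeremateng import KyerematengFit
from .pcsaft import Mixture, _GammaTracker, lle_curve, spinodal_window
from .pcsaft import sle_temperature as pcsaft_sle_temperature
from .tg_models import TgFit, simha_boyer_K, tg_gt, tg_kwei

__all__ = ["Curve", "PhaseDiagram", "assemble", "classify", "max_stable_loading"]

REGIONS = ("stable solution", "supersaturated", "LLE metastable", "LLE unstable")


@dataclass
class Curve:
    kind: str  # SLE | binodal | spinodal | Tg
    model: str  # fh | ky1 | ky2 | pcsaft | gt / kwei tag
    w_pct: np.ndarray  # drug load, % w/w, increasing
    T: np.ndarray  # K

    def interp(self, w_pct) -> np.ndarray:
        """Temperature at drug load(s) by linear interpolation (NaN outside)."""
        return np.interp(np.asarray(w_pct, dtype=float), self.w_pct, self.T,
                         left=np.nan, right=np.nan)


@dataclass
class PhaseDiagram:
    pair: tuple[str, str]
    api: CompoundThermo
    poly: CompoundThermo
    curves: list[Curve] = field(default_factory=list)

    def curve(self, kind: str, model: str | None = None) -> Curve:
        for c in self.curves:
            if c.kind == kind and (model is None or c.model == model):
                return c
        raise KeyError(f"no {kind} curve" + (f" for model {model}" if model else ""))

    def has_curve(self, kind: str, model: str | None = None) -> bool:
        try:
            self.curve(kind, model)
            return True
        except KeyError:
            return False

    def models(self, kind: str = "SLE") -> list[str]:
        return [c.model for c in self.curves if c.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.curves:
            for w, T in zip(c.w_pct, c.T):
                rows.append({"curve": c.kind, "model": c.model,
                             "w_pct": w, "T_K": T})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# curve construction


def _fh_sle(model: FHModel, w_pct: np.ndarray) -> Curve:
    T = np.full(w_pct.shape, np.nan)
    for i, wp in enumerate(w_pct):
        phi = convert_composition(wp / 100.0, "w", "phi", model.api, model.poly)
        try:
            T[i] = fh_sle_temperature(model, phi)
        except ValueError:
            pass  # solubility temperature below the search window
    ok = ~np.isnan(T)
    return Curve(kind="SLE", model="fh", w_pct=w_pct[ok], T=T[ok])


def _fh_domes(model: FHModel, T_min: float, n_T: int = 60) -> list[Curve]:
    """Binodal and spinodal domes of the FH model between T_min and T_c."""
    m = model.m
    phi_c, chi_c = critical_point(m)
    # T_c solves chi(T) = chi_c (UCST: chi grows as T falls)
    if model.B <= 0 or model.chi(T_min) <= chi_c:
        return []
    T_c = model.B / (chi_c - model.A)
    out = []
    Ts = np.linspace(T_min, T_c - 1e-6, n_T)
    bin_lo, bin_hi, spin_lo, spin_hi, T_ok = [], [], [], [], []
    for T in Ts:
        sp = spinodal_phis(m, model.chi(T))
        if sp is None:
            continue
        try:
            bn = fh_binodal(model, T)
        except (ValueError, RuntimeError):
            continue
        T_ok.append(T)
        spin_lo.append(sp[0])
        spin_hi.append(sp[1])
        bin_lo.append(bn[0])
        bin_hi.append(bn[1])
    if not T_ok:
        return []

    def dome(lo, hi, kind):
        # assemble the dome as w(T-branches) merged into one increasing-w curve
        phis = np.concatenate([lo[::-1], [phi_c], hi])
        temps = np.concatenate([np.asarray(T_ok)[::-1], [T_c], T_ok])
        w = np.array([
            100.0 * convert_composition(p, "phi", "w", model.api, model.poly)
            for p in phis
        ])
        order = np.argsort(w)
        return Curve(kind=kind, model="fh", w_pct=w[order], T=temps[order])

    out.append(dome(np.array(bin_lo), np.array(bin_hi), "binodal"))
    out.append(dome(np.array(spin_lo), np.array(spin_hi), "spinodal"))
    return out


def _ky_sle(fit: KyerematengFit, w_pct: np.ndarray) -> Curve:
    tag = "ky1" if fit.mode == "one_step" else "ky2"
    return Curve(kind="SLE", model=tag, w_pct=w_pct, T=fit.ts(w_pct))


def _pcsaft_sle(mix: Mixture, api: CompoundThermo, poly: CompoundThermo,
                w_pct: np.ndarray, n_model: int = 41) -> Curve:
    """SLE on a coarse model grid, interpolated onto the canvas grid.

    Each point is a saturation-temperature solve; the curve is smooth, so
    a 41-point model grid interpolates onto any canvas grid to well below
    experimental resolution.
    """
    w_model = np.linspace(w_pct.min(), w_pct.max(), min(n_model, w_pct.size))
    tracker = _GammaTracker(mix)
    T = np.full(w_model.shape, np.nan)
    for i, wp in enumerate(w_model):
        if wp >= 100.0:
            T[i] = api.Tm
            continue
        x = convert_composition(wp / 100.0, "w", "x", api, poly)
        try:
            T[i] = pcsaft_sle_temperature(mix, api, x, tracker=tracker, t_lo=150.0)
        except RuntimeError:
            pass
    ok = ~np.isnan(T)
    return Curve(kind="SLE", model="pcsaft", w_pct=w_pct,
                 T=np.interp(w_pct, w_model[ok], T[ok]))


def _pcsaft_domes(mix: Mixture, api: CompoundThermo, poly: CompoundThermo,
                  T_grid: np.ndarray) -> list[Curve]:
    """Isoactivity binodal and finite-difference spinodal domes."""
    res = lle_curve(mix, T_grid)
    bin_pts, spin_pts = [], []
    for r in res:
        if r.converged:
            for xv in (r.x_L1, r.x_L2):
                bin_pts.append((100.0 * convert_composition(xv, "x", "w", api, poly), r.T))
    for T in T_grid:
        win = spinodal_window(mix, float(T))
        if win is not None:
            for xv in win:
                spin_pts.append((100.0 * convert_composition(xv, "x", "w", api, poly), float(T)))
    out = []
    for kind, pts in (("binodal", bin_pts), ("spinodal", spin_pts)):
        if pts:
            arr = np.array(sorted(pts))
            out.append(Curve(kind=kind, model="pcsaft", w_pct=arr[:, 0], T=arr[:, 1]))
    return out


def _tg_curve(api: CompoundThermo, poly: CompoundThermo, w_pct: np.ndarray,
              tg: TgFit | None) -> Curve:
    w = w_pct / 100.0
    if tg is None:
        K = simha_boyer_K(api, poly)
        return Curve(kind="Tg", model="gt_simha_boyer", w_pct=w_pct,
                     T=tg_gt(w, api, poly, K))
    return Curve(kind="Tg", model=tg.model.value.lower(), w_pct=w_pct,
                 T=tg_kwei(w, api, poly, tg.K, tg.q))


def assemble(api: CompoundThermo, poly: CompoundThermo, *,
             fh: FHModel | None = None,
             ky: KyerematengFit | None = None,
             pcsaft: Mixture | None = None,
             tg: TgFit | None = None,
             w_pct_grid: np.ndarray | None = None,
             T_min: float = 273.15,
             pcsaft_lle: bool = True,
             n_T_lle: int = 25) -> PhaseDiagram:
    """Build a unified phase diagram from whichever models were fitted.

    At least one SLE-capable model (``fh``, ``ky`` or ``pcsaft``) is
    required; the Tg overlay defaults to Gordon-Taylor with the
    Simha-Boyer constant when no fitted Tg model is given.
    """
    if fh is None and ky is None and pcsaft is None:
        raise ValueError("at least one fitted SLE model is required")
    if w_pct_grid is None:
        w_pct_grid = np.linspace(0.5, 100.0, 201)
    w_pct_grid = np.asarray(w_pct_grid, dtype=float)
    diagram = PhaseDiagram(pair=(api.name, poly.name), api=api, poly=poly)
    if fh is not None:
        diagram.curves.append(_fh_sle(fh, w_pct_grid))
        diagram.curves.extend(_fh_domes(fh, T_min))
    if ky is not None:
        diagram.curves.append(_ky_sle(ky, w_pct_grid))
    if pcsaft is not None:
        diagram.curves.append(_pcsaft_sle(pcsaft, api, poly, w_pct_grid))
        if pcsaft_lle:
            T_grid = np.linspace(T_min, api.Tm, n_T_lle)
            diagram.curves.extend(_pcsaft_domes(pcsaft, api, poly, T_grid))
    diagram.curves.append(_tg_curve(api, poly, w_pct_grid, tg))
    return diagram


# ---------------------------------------------------------------------------
# region classification


def classify(diagram: PhaseDiagram, w_pct: float, T: float,
             model: str | None = None) -> str:
    """Label the region at drug load ``w_pct`` (% w/w) and temperature T (K).

    ``model`` picks whose curves to classify against (defaults to the
    first SLE model on the diagram).  The label is one of REGIONS with a
    " (glassy)" suffix when T is below the blend Tg.
    """
    if model is None:
        model = diagram.models("SLE")[0]
    sle = diagram.curve("SLE", model)
    T_sle = float(np.interp(w_pct, sle.w_pct, sle.T))
    dissolved = T >= T_sle

    label = "stable solution" if dissolved else "supersaturated"
    for kind, tag in (("spinodal", "LLE unstable"), ("binodal", "LLE metastable")):
        if diagram.has_curve(kind, model):
            c = diagram.curve(kind, model)
            T_dome = c.interp(w_pct)
            if np.isfinite(T_dome) and T < T_dome:
                label = tag
                break

    tgc = diagram.curve("Tg")
    if T < float(np.interp(w_pct, tgc.w_pct, tgc.T)):
        label += " (glassy)"
    return label


def max_stable_loading(diagram: PhaseDiagram, T: float,
                       model: str | None = None, n: int = 2001) -> float:
    """Largest drug load (% w/w) classified 'stable solution' at T.

    Scanned on a fine composition grid; monotone non-decreasing in T for
    UCST systems.
    """
    if model is None:
        model = diagram.models("SLE")[0]
    sle = diagram.curve("SLE", model)
    if not (sle.T.min() - 1e-9 <= T <= sle.T.max() + 1e-9):
        raise ValueError(
            f"T={T:g} K outside the {model} SLE curve range "
            f"({sle.T.min():.1f}, {sle.T.max():.1f}) K")
    ws = np.linspace(diagram.curve("SLE", model).w_pct.min(), 100.0, n)
    stable = np.array([
        classify(diagram, float(w), T, model=model).startswith("stable")
        for w in ws
    ])
    if not stable.any():
        return 0.0
    return float(ws[np.nonzero(stable)[0][-1]])


def plot(diagram: PhaseDiagram, path: str | Path | None = None):
    """Render the diagram with matplotlib (thin optional layer; all the
    science lives in the exported tables)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    styles = {"SLE": "-", "binodal": "--", "spinodal": ":", "Tg": "-."}
    for c in diagram.curves:
        ax.plot(c.w_pct, c.T - 273.15, styles.get(c.kind, "-"),
                label=f"{c.kind} ({c.model})")
    ax.set_xlabel("drug load (% w/w)")
    ax.set_ylabel("temperature (\N{DEGREE SIGN}C)")
    ax.set_title(" - ".join(diagram.pair))
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
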