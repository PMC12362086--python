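"""Empirical solubility-temperature fitting T_s = -A exp(b x) + T_m + C.

``x`` is the drug content in percent w/w (0-100); with A > 0 and b < 0 the
curve rises monotonically toward the pure-drug melting point.  Two fitting
strategies are provided:

* one-step: C = 0 and b fixed (default -0.05, the literature consensus for
  drug-polymer blends); only A is fitted, which is linear least squares.
  A ``free_b`` variant fits (A, b) with C = 0.
* two-step: stage 1 fits (A, b) with C = 0; stage 2 fits C holding (A, b);
  a final joint polish of all three parameters, started from the staged
  estimates, is run by default so that noise-free data generated from any
  (A, b, C) is recovered exactly.  ``polish=False`` gives the literal
  staged estimates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core import CompoundThermo, FitReport, MPDDataset

__all__ = ["KyerematengFit", "ky_ts", "fit_one_step", "fit_two_step", "ky_curve"]

DEFAULT_B = -0.05  # per percent w/w


@dataclass(frozen=True)
class KyerematengFit:
    """Fitted parameters and provenance of the constraint set used."""

    A: float  # K
    b: float  # 1/(% w/w), negative for melting-point depression
    C: float  # K
    Tm: float  # K, pure-API melting end-set
    mode: str  # one_step | two_step
    frozen: tuple[str, ...]  # parameters that were held fixed
    report: FitReport
    staged: dict | None = None  # intermediate estimates for two_step
    x_min_observed: float = 0.0  # % w/w; below this the curve is extrapolation

    def ts(self, x):
        return ky_ts(x, self.A, self.b, self.C, self.Tm)


def ky_ts(x, A, b, C, Tm):
    """Evaluate T_s = -A exp(b x) + Tm + C with x in % w/w."""
    x = np.asarray(x, dtype=float)
    out = -A * np.exp(b * x) + Tm + C
    return float(out) if out.ndim == 0 else out


def _data(ds: MPDDataset, api: CompoundThermo):
    w, T = ds.active()
    return 100.0 * w, T  # % w/w


def fit_one_step(ds: MPDDataset, api: CompoundThermo,
                 b_fixed: float = DEFAULT_B, free_b: bool = False) -> KyerematengFit:
    """One-step fit: C = 0 and (unless ``free_b``) b fixed; A by least squares.

    With b fixed the problem is linear: A = sum(e(Tm - T)) / sum(e^2) with
    e = exp(b x).
    """
    x, T = _data(ds, api)
    Tm = api.Tm
    if free_b:
        A0 = max(Tm - float(np.min(T)), 1e-6)

        def resid(p):
            return ky_ts(x, p[0], p[1], 0.0, Tm) - T

        # physical branch: positive amplitude, decaying exponential
        sol = optimize.least_squares(resid, [A0, b_fixed], method="trf",
                                     bounds=([0.0, -1.0], [np.inf, 0.0]))
        A, b = map(float, sol.x)
        frozen = ("C",)
    else:
        e = np.exp(b_fixed * x)
        A = float(np.dot(e, Tm - T) / np.dot(e, e))
        b = b_fixed
        frozen = ("b", "C")
    pred = ky_ts(x, A, b, 0.0, Tm)
    return KyerematengFit(
        A=A, b=b, C=0.0, Tm=Tm, mode="one_step", frozen=frozen,
        report=FitReport.from_predictions("kyeremateng_one_step",
                                          {"A": A, "b": b, "C": 0.0}, T, pred),
        x_min_observed=float(np.min(x)),
    )


def fit_two_step(ds: MPDDataset, api: CompoundThermo,
                 polish: bool = True) -> KyerematengFit:
    """Two-step fit: (A, b) with C = 0, then C, then (optionally) a joint polish.

    The staged estimates are kept on the result (``staged``) regardless of
    polishing.  Initialization is deterministic: A0 = Tm - min(T_s),
    b0 = -0.05, C0 = 0.
    """
    x, T = _data(ds, api)
    Tm = api.Tm
    A0 = max(Tm - float(np.min(T)), 1e-6)

    def resid_ab(p):
        return ky_ts(x, p[0], p[1], 0.0, Tm) - T

    # multi-start over b; each start uses the exact linear-in-A optimum for
    # that b, so stage 1 always dominates any fixed-b constrained fit
    best = None
    for b0 in (-0.03, DEFAULT_B, -0.08):
        e = np.exp(b0 * x)
        A_b0 = max(float(np.dot(e, Tm - T) / np.dot(e, e)), 1e-9)
        sol = optimize.least_squares(resid_ab, [A_b0, b0], method="trf",
                                     bounds=([0.0, -1.0], [np.inf, 0.0]))
        if best is None or sol.cost < best.cost:
            best = sol
    stage1 = best
    A1, b1 = map(float, stage1.x)
    # stage 2: C is the mean residual given (A1, b1) -- linear least squares
    C2 = float(np.mean(T - ky_ts(x, A1, b1, 0.0, Tm)))
    staged = {
        "stage1": {"A": A1, "b": b1, "ssr": float(2 * stage1.cost)},
        "stage2": {"C": C2, "ssr": float(np.sum((ky_ts(x, A1, b1, C2, Tm) - T) ** 2))},
    }
    A, b, C = A1, b1, C2
    if polish:
        def resid_abc(p):
            return ky_ts(x, p[0], p[1], p[2], Tm) - T

        sol = optimize.least_squares(
            resid_abc, [max(A1, 1e-9), b1, C2], method="trf",
            bounds=([0.0, -1.0, -np.inf], [np.inf, 0.0, np.inf]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if np.sum(sol.fun**2) <= staged["stage2"]["ssr"] + 1e-12:
            A, b, C = map(float, sol.x)
    pred = ky_ts(x, A, b, C, Tm)
    return KyerematengFit(
        A=A, b=b, C=C, Tm=Tm, mode="two_step", frozen=(),
        report=FitReport.from_predictions("kyeremateng_two_step",
                                          {"A": A, "b": b, "C": C}, T, pred),
        staged=staged,
        x_min_observed=float(np.min(x)),
    )


def ky_curve(fit: KyerematengFit, x_grid) -> np.ndarray:
    """Evaluate the fitted curve on an x grid (% w/w).

    Returns shape (n, 3): (x, T_s K, extrapolated flag) where the flag is 1
    below the smallest observed composition.
    """
    x = np.asarray(x_grid, dtype=float)
    T = fit.ts(x)
    return np.column_stack([x, T, (x < fit.x_min_observed).astype(float)])
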