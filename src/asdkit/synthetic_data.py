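"""Synthetic melting-point-depression and Tg datasets with known truth.

Every fitting stage in the package (Flory-Huggins chi extraction, the
Kyeremateng empirical fit, PC-SAFT k_ij, Tg mixing rules) gets a
download-free parameter-recovery test by generating data from the exact
model being fitted and adding seeded Gaussian noise.

The default design mirrors a DSC melting-point-depression study on
drug-polymer physical mixtures: drug loadings from 30 to 95 % w/w in
5 % steps, end-set temperature noise of 0.5 K (typical end-set
repeatability), and Tg read from the second heating cycle at the same
compositions plus the pure endpoints (anchored noise-free, as pure
references).  What these data do *not* emulate: viscosity-driven
plateaus at high polymer content, heating-rate artifacts, or any
composition dependence of chi -- real datasets carry such points, which
is why the dataset type has an ``excluded`` mechanism.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import CompoundThermo, MPDDataset, TgDataset, convert_composition
from .flory_huggins import FHModel, sle_temperature as fh_sle_temperature
from .kyeremateng import ky_ts
from .pcsaft import KijModel, Mixture, PcSaftParams, _GammaTracker
from .pcsaft import sle_temperature as pcsaft_sle_temperature
from .tg_models import tg_kwei

__all__ = ["SyntheticSpec", "default_compositions", "generate_mpd", "generate_tg"]


def default_compositions() -> np.ndarray:
    """Drug mass fractions 0.30 ... 0.95 in 0.05 steps (the DSC design)."""
    return np.round(np.arange(0.30, 0.951, 0.05), 10)


@dataclass
class SyntheticSpec:
    """Ground-truth description of a simulated MPD/Tg experiment.

    ``generator`` picks the noise-free model: "fh" uses chi(T) = A + B/T
    in the Flory-Huggins SLE relation; "kyeremateng" evaluates
    T_s = -A exp(b x) + Tm + C; "pcsaft" solves the equation-of-state SLE
    at the given k_ij.  ``tg_generator`` is always the Kwei model (k, q).
    """

    generator: str = "fh"  # fh | kyeremateng | pcsaft
    params: dict = field(default_factory=lambda: {"A": -2.0, "B": 1000.0})
    compositions: np.ndarray = field(default_factory=default_compositions)
    noise_sd: float = 0.5  # K
    seed: int = 0
    tg_params: dict = field(default_factory=lambda: {"k": 0.6, "q": -30.0})
    noise_sd_tg: float = 1.0  # K

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.noise_sd_tg < 0:
            raise ValueError("noise standard deviations must be >= 0")
        self.compositions = np.asarray(self.compositions, dtype=float)


def _noise_free_mpd(spec: SyntheticSpec, api: CompoundThermo,
                    poly: CompoundThermo,
                    pcsaft_pair: tuple[PcSaftParams, PcSaftParams] | None) -> np.ndarray:
    w = spec.compositions
    if spec.generator == "fh":
        model = FHModel(api=api, poly=poly, A=spec.params["A"], B=spec.params["B"])
        T = np.array([
            fh_sle_temperature(model, convert_composition(float(wi), "w", "phi", api, poly))
            for wi in w
        ])
    elif spec.generator == "kyeremateng":
        p = spec.params
        T = ky_ts(100.0 * w, p["A"], p["b"], p.get("C", 0.0), api.Tm)
    elif spec.generator == "pcsaft":
        if pcsaft_pair is None:
            raise ValueError("pcsaft generator needs (api, polymer) PcSaftParams")
        mix = Mixture(list(pcsaft_pair), kij=KijModel(k_int=spec.params.get("kij", 0.0)))
        tracker = _GammaTracker(mix)
        T = np.array([
            pcsaft_sle_temperature(
                mix, api, convert_composition(float(wi), "w", "x", api, poly),
                tracker=tracker, t_lo=150.0)
            for wi in w
        ])
    else:
        raise ValueError(f"unknown generator {spec.generator!r}")
    if np.any(np.diff(T[np.argsort(w)]) < -1e-9):
        # e.g. FH truths whose chi is high enough for incipient demixing:
        # the noise-free curve then rises and falls instead of depressing
        # monotonically -- usable for round-trip fits, but flagged
        warnings.warn("noise-free generating curve is not monotone in w",
                      stacklevel=2)
    return T


def generate_mpd(spec: SyntheticSpec, api: CompoundThermo, poly: CompoundThermo,
                 pcsaft_pair: tuple[PcSaftParams, PcSaftParams] | None = None
                 ) -> MPDDataset:
    """Simulate one melting-point-depression dataset.

    End-set temperatures come from the exact generating model plus
    N(0, noise_sd^2); the noise-free curve is checked for monotone
    depression before noise is added.  Same seed, same dataset.
    """
    T = _noise_free_mpd(spec, api, poly, pcsaft_pair)
    rng = np.random.default_rng(spec.seed)
    T_obs = T + rng.normal(0.0, spec.noise_sd, T.shape) if spec.noise_sd > 0 else T
    return MPDDataset(
        api=api.name, polymer=poly.name,
        points=list(zip(spec.compositions, T_obs)),
        heating_rate=1.0,
    )


def generate_tg(spec: SyntheticSpec, api: CompoundThermo,
                poly: CompoundThermo) -> TgDataset:
    """Simulate one blend-Tg dataset from the Kwei model.

    Noise applies only to interior compositions; the pure endpoints are
    anchored at the tabulated component Tg values (pure references are
    measured separately and far more precisely than blends).
    """
    w_mid = spec.compositions
    k, q = spec.tg_params["k"], spec.tg_params["q"]
    Tg_mid = tg_kwei(w_mid, api, poly, k, q)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_tg > 0:
        Tg_mid = Tg_mid + rng.normal(0.0, spec.noise_sd_tg, Tg_mid.shape)
    w = np.concatenate([[0.0], w_mid, [1.0]])
    Tg = np.concatenate([[poly.Tg], Tg_mid, [api.Tg]])
    return TgDataset(api=api.name, polymer=poly.name, points=list(zip(w, Tg)))
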