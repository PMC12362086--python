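"""Shared data model, unit handling and fit diagnostics.

Everything downstream (Flory-Huggins, PC-SAFT, empirical fits, Tg mixing
rules) works on the records defined here.  Conventions:

* temperatures are stored in Kelvin, energies in J/mol, heat capacities in
  J/(mol K), densities in g/cm3, molar masses in g/mol;
* compositions can be expressed as mass fraction ``w``, mole fraction ``x``
  or volume fraction ``phi`` of the drug (API); conversions between the
  three bases go through the two compounds' molar masses and true
  densities and round-trip to machine precision;
* fit quality is reported as AARD (average absolute relative deviation, %)
  and ARD (its signed counterpart).
"""
from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "R",
    "Role",
    "CompoundThermo",
    "Composition",
    "MPDDataset",
    "TgDataset",
    "FitReport",
    "aard",
    "ard",
    "convert_composition",
    "load_compounds",
    "load_mpd",
    "load_tg",
]

#: molar gas constant, J/(mol K)
R = 8.31446261815324

_T0C = 273.15


class Role(str, enum.Enum):
    API = "API"
    polymer = "polymer"


def _to_kelvin(value: float, unit: str) -> float:
    unit = unit.strip().upper().lstrip("°")
    if unit == "K":
        return float(value)
    if unit == "C":
        return float(value) + _T0C
    raise ValueError(f"unknown temperature unit {unit!r} (use 'C' or 'K')")


@dataclass(frozen=True)
class CompoundThermo:
    """Pure-component thermodynamic record.

    Parameters
    ----------
    name : str
        Compound identifier.
    role : Role
        ``API`` (small-molecule drug) or ``polymer``.
    Mw : float
        Molar mass, g/mol.
    rho : float
        True (pycnometric) density, g/cm3, taken temperature-independent.
    Tg : float
        Glass-transition temperature, K.
    Tm : float, optional
        Melting end-set temperature, K (crystalline APIs only).
    dHfus : float, optional
        Molar enthalpy of fusion, J/mol.
    dCp : float, optional
        Liquid minus solid molar heat capacity, J/(mol K).
    """

    name: str
    role: Role
    Mw: float
    rho: float
    Tg: float
    Tm: float | None = None
    dHfus: float | None = None
    dCp: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", Role(self.role))
        for attr in ("Mw", "rho", "Tg"):
            v = getattr(self, attr)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{self.name}: {attr} must be finite and > 0, got {v}")
        if self.Tm is not None:
            if not self.Tm > self.Tg:
                raise ValueError(
                    f"{self.name}: Tm ({self.Tm} K) must exceed Tg ({self.Tg} K)"
                )
            if self.dHfus is None or not self.dHfus > 0:
                raise ValueError(f"{self.name}: Tm given but dHfus missing or <= 0")

    @property
    def molar_volume(self) -> float:
        """Molar volume Mw/rho, cm3/mol."""
        return self.Mw / self.rho

    @classmethod
    def from_dict(cls, d: Mapping) -> "CompoundThermo":
        unit = str(d.get("temperature_unit", "K"))
        Tm = d.get("Tm")
        dHfus = d.get("dHfus_kJ_mol")
        return cls(
            name=str(d["name"]),
            role=Role(d["role"]),
            Mw=float(d["Mw"]),
            rho=float(d["rho"]),
            Tg=_to_kelvin(float(d["Tg"]), unit),
            Tm=None if Tm is None else _to_kelvin(float(Tm), unit),
            dHfus=None if dHfus is None else float(dHfus) * 1e3,
            dCp=None if d.get("dCp_J_mol_K") is None else float(d["dCp_J_mol_K"]),
        )

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "role": self.role.value,
            "Mw": self.Mw,
            "rho": self.rho,
            "Tg": self.Tg,
            "temperature_unit": "K",
        }
        if self.Tm is not None:
            d["Tm"] = self.Tm
            d["dHfus_kJ_mol"] = self.dHfus / 1e3
            d["dCp_J_mol_K"] = self.dCp
        return d


# ---------------------------------------------------------------------------
# composition bases

_BASES = ("w", "x", "phi")


def _w_to_phi(w, api: CompoundThermo, poly: CompoundThermo):
    return (w / api.rho) / (w / api.rho + (1.0 - w) / poly.rho)


def _phi_to_w(phi, api: CompoundThermo, poly: CompoundThermo):
    return (phi * api.rho) / (phi * api.rho + (1.0 - phi) * poly.rho)


def _w_to_x(w, api: CompoundThermo, poly: CompoundThermo):
    return (w / api.Mw) / (w / api.Mw + (1.0 - w) / poly.Mw)


def _x_to_w(x, api: CompoundThermo, poly: CompoundThermo):
    return (x * api.Mw) / (x * api.Mw + (1.0 - x) * poly.Mw)


def convert_composition(value, from_basis: str, to_basis: str,
                        api: CompoundThermo, poly: CompoundThermo):
    """Convert an API fraction between mass (w), mole (x) and volume (phi) bases.

    Accepts scalars or arrays; values must lie in [0, 1].
    """
    if from_basis not in _BASES or to_basis not in _BASES:
        raise ValueError(f"basis must be one of {_BASES}")
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("composition must be finite and within [0, 1]")
    if from_basis == to_basis:
        return value
    # hub through mass fraction
    if from_basis == "w":
        w = arr
    elif from_basis == "phi":
        w = _phi_to_w(arr, api, poly)
    else:
        w = _x_to_w(arr, api, poly)
    if to_basis == "w":
        out = w
    elif to_basis == "phi":
        out = _w_to_phi(w, api, poly)
    else:
        out = _w_to_x(w, api, poly)
    return float(out) if np.isscalar(value) or np.ndim(value) == 0 else out


@dataclass(frozen=True)
class Composition:
    """API content of a binary blend on all three bases simultaneously."""

    w_API: float
    x_API: float
    phi_API: float

    @classmethod
    def from_any(cls, value: float, basis: str, api: CompoundThermo,
                 poly: CompoundThermo) -> "Composition":
        w = convert_composition(value, basis, "w", api, poly)
        return cls(
            w_API=w,
            x_API=convert_composition(w, "w", "x", api, poly),
            phi_API=convert_composition(w, "w", "phi", api, poly),
        )


# ---------------------------------------------------------------------------
# datasets


@dataclass
class MPDDataset:
    """Melting-point-depression observations for one API/polymer pair.

    ``points`` is a sequence of (w_API mass fraction, end-set temperature K).
    ``excluded`` holds indices flagged out of fits (e.g. high-viscosity
    plateau points); they stay in the dataset for provenance.
    """

    api: str
    polymer: str
    points: Sequence[tuple[float, float]]
    heating_rate: float | None = None  # K/min, metadata only
    excluded: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        pts = [(float(w), float(T)) for w, T in self.points]
        for i, (w, T) in enumerate(pts):
            if not (0.0 < w <= 1.0):
                raise ValueError(f"point {i}: w_API must be in (0, 1], got {w}")
            if not (np.isfinite(T) and T > 0):
                raise ValueError(f"point {i}: T_end must be positive, got {T}")
        self.points = pts
        bad = [i for i in self.excluded if not (0 <= i < len(pts))]
        if bad:
            raise ValueError(f"excluded indices out of range: {bad}")

    @property
    def n_active(self) -> int:
        return len(self.points) - len(set(self.excluded))

    def active(self) -> tuple[np.ndarray, np.ndarray]:
        """(w, T) arrays of the non-excluded points."""
        excl = set(self.excluded)
        sel = [(w, T) for i, (w, T) in enumerate(self.points) if i not in excl]
        if len(sel) < 3:
            raise ValueError("at least 3 non-excluded points are required for a fit")
        arr = np.array(sel, dtype=float)
        return arr[:, 0], arr[:, 1]

    def check_against(self, api: CompoundThermo, tol: float = 2.0) -> None:
        """Validate that no end-set temperature exceeds the API melting point."""
        if api.Tm is None:
            raise ValueError(f"{api.name} has no melting point on record")
        for i, (_, T) in enumerate(self.points):
            if T > api.Tm + tol:
                raise ValueError(
                    f"point {i}: T_end {T:.2f} K exceeds Tm {api.Tm:.2f} K + {tol} K"
                )


@dataclass
class TgDataset:
    """Blend glass-transition observations: (w_API, Tg K)."""

    api: str
    polymer: str
    points: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        pts = [(float(w), float(T)) for w, T in self.points]
        for i, (w, T) in enumerate(pts):
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"point {i}: w_API must be in [0, 1], got {w}")
            if not T > 0:
                raise ValueError(f"point {i}: Tg must be positive, got {T}")
        self.points = pts

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.array(self.points, dtype=float)
        return arr[:, 0], arr[:, 1]


# ---------------------------------------------------------------------------
# fit diagnostics


def aard(measured, predicted) -> float:
    """Average absolute relative deviation, percent.

    AARD = (100/N) * sum |T_meas - T_pred| / T_meas
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.size == 0:
        raise ValueError("measured and predicted must have equal nonzero length")
    if np.any(m == 0):
        raise ValueError("measured values must be nonzero")
    return float(100.0 * np.mean(np.abs(m - p) / np.abs(m)))


def ard(measured, predicted) -> float:
    """Signed mean relative deviation, percent (positive: model under-predicts)."""
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.size == 0:
        raise ValueError("measured and predicted must have equal nonzero length")
    if np.any(m == 0):
        raise ValueError("measured values must be nonzero")
    return float(100.0 * np.mean((m - p) / m))


@dataclass
class FitReport:
    """Fitted parameters plus deviation diagnostics for any model."""

    model: str
    params: dict[str, float]
    aard_pct: float
    ard_pct: float
    n_points: int
    residuals: list[float]

    @classmethod
    def from_predictions(cls, model: str, params: Mapping[str, float],
                         measured, predicted) -> "FitReport":
        m = np.asarray(measured, dtype=float)
        p = np.asarray(predicted, dtype=float)
        return cls(
            model=model,
            params=dict(params),
            aard_pct=aard(m, p),
            ard_pct=ard(m, p),
            n_points=int(m.size),
            residuals=list(map(float, m - p)),
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "aard_pct": self.aard_pct,
            "ard_pct": self.ard_pct,
            "n_points": self.n_points,
            "residuals": self.residuals,
        }


# ---------------------------------------------------------------------------
# I/O


def load_compounds(path: str | Path) -> dict[str, CompoundThermo]:
    """Read a compound registry from a JSON list of records.

    Temperatures may be in Celsius or Kelvin (``temperature_unit`` per
    record); enthalpies in kJ/mol (``dHfus_kJ_mol``).  Duplicate names and
    invalid records raise with the offending entry number.
    """
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, list):
        raise ValueError("compound registry must be a JSON list")
    registry: dict[str, CompoundThermo] = {}
    for i, rec in enumerate(raw):
        try:
            c = CompoundThermo.from_dict(rec)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"compound record {i}: {exc}") from exc
        if c.name in registry:
            raise ValueError(f"duplicate compound name {c.name!r} (record {i})")
        registry[c.name] = c
    return registry


def _read_table(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    return df


def load_mpd(path: str | Path, api: str = "", polymer: str = "",
             heating_rate: float | None = None) -> MPDDataset:
    """Read an MPD table (columns: w_api, T_end, unit) into a dataset.

    Rows failing validation are reported with their (1-based) row numbers.
    """
    df = _read_table(path, ["w_api", "T_end", "unit"])
    if len(df) < 3:
        raise ValueError(f"{path}: at least 3 points are required, got {len(df)}")
    points = []
    errors = []
    for i, row in df.iterrows():
        try:
            points.append((float(row["w_api"]), _to_kelvin(row["T_end"], str(row["unit"]))))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i + 1}: {exc}")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    return MPDDataset(api=api, polymer=polymer, points=points, heating_rate=heating_rate)


def load_tg(path: str | Path, api: str = "", polymer: str = "") -> TgDataset:
    """Read a Tg table (columns: w_api, Tg, unit) into a dataset."""
    df = _read_table(path, ["w_api", "Tg", "unit"])
    points = []
    errors = []
    for i, row in df.iterrows():
        try:
            points.append((float(row["w_api"]), _to_kelvin(row["Tg"], str(row["unit"]))))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i + 1}: {exc}")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    return TgDataset(api=api, polymer=polymer, points=points)


def save_mpd(ds: MPDDataset, path: str | Path) -> None:
    pd.DataFrame(
        {"w_api": [w for w, _ in ds.points],
         "T_end": [T for _, T in ds.points],
         "unit": "K"}
    ).to_csv(path, index=False)


def save_tg(ds: TgDataset, path: str | Path) -> None:
    pd.DataFrame(
        {"w_api": [w for w, _ in ds.points],
         "Tg": [T for _, T in ds.points],
         "unit": "K"}
    ).to_csv(path, index=False)
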