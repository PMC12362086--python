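"""Group-contribution solubility-parameter screening.

Implements the Fedors (single cohesive-energy contribution) and
Hoftyzer-van Krevelen / Just-Breitkreutz (partitioned Hansen components)
calculators over per-molecule functional-group inventories, plus the
derived screening quantities used to rank drug-polymer pairs:

* total-parameter difference ``delta_delta_t = delta_t(API) - delta_t(polymer)``
  with the 7 / 10 MPa^(1/2) rule-of-thumb verdict,
* Bagley-plane distance ``R_av = sqrt(4*(dv_p - dv_a)^2 + (dh_p - dh_a)^2)``,
* a solubility-parameter-derived Flory-Huggins interaction parameter
  ``chi = V0 * (delta_API - delta_poly)^2 / (R T)``.

The bundled group tables and inventories under ``asdkit/data`` are
*illustrative* transcriptions of standard published compilations, shipped
so the pipeline runs end to end; they are editable data, not a canonical
chemistry, and numbers computed from them should not be read as anything
more than a demonstration.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import R, CompoundThermo

__all__ = [
    "GCMethod",
    "GroupTable",
    "GroupInventory",
    "SolubilityParams",
    "ScreenResult",
    "fedors_delta",
    "hvk_delta",
    "compute_delta",
    "bagley_distance",
    "chi_from_delta",
    "screen_pair",
    "load_group_table",
    "load_inventory",
]

#: rule-of-thumb thresholds on |delta_delta_t|, MPa^(1/2)
SOLUBLE_THRESHOLD = 7.0
IMMISCIBLE_THRESHOLD = 10.0


class GCMethod(str, enum.Enum):
    Fedors = "Fedors"
    HVK = "HVK"
    JB = "JB"


@dataclass(frozen=True)
class GroupTable:
    """Group-contribution coefficient table.

    ``rows`` maps group name to a dict with keys ``E`` (cohesive energy,
    J/mol; Fedors), ``Fd``/``Fp`` ((J cm3)^(1/2)/mol), ``Eh`` (J/mol) and
    ``V`` (molar volume contribution, cm3/mol).  Fedors rows carry (E, V)
    only; HVK/JB rows carry (Fd, Fp, Eh, V).
    """

    method: GCMethod
    rows: Mapping[str, Mapping[str, float]]
    source: str = ""

    def __post_init__(self) -> None:
        for g, row in self.rows.items():
            if not row.get("V", 0.0) > 0:
                raise ValueError(f"group {g!r}: V must be > 0")
            if self.method is GCMethod.Fedors:
                if not np.isfinite(row.get("E", np.nan)):
                    raise ValueError(f"group {g!r}: Fedors row needs E")
            else:
                for k in ("Fd", "Fp", "Eh"):
                    if not np.isfinite(row.get(k, np.nan)):
                        raise ValueError(f"group {g!r}: {self.method.value} row needs {k}")


@dataclass(frozen=True)
class GroupInventory:
    """Functional-group multiplicities for one molecule or repeat unit.

    Fractional counts are allowed (copolymer repeat units weighted by
    monomer ratio); the basis cancels out of every intensive quantity.
    """

    compound: str
    counts: Mapping[str, float]

    def __post_init__(self) -> None:
        if not any(c > 0 for c in self.counts.values()):
            raise ValueError(f"{self.compound}: inventory needs at least one nonzero count")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError(f"{self.compound}: negative group counts")


@dataclass(frozen=True)
class SolubilityParams:
    """Hansen/Hildebrand solubility parameters, MPa^(1/2).

    Fedors populates ``delta_t`` only; HVK/JB populate the components with
    ``delta_t^2 = delta_d^2 + delta_p^2 + delta_h^2`` and the Bagley
    combination ``delta_v^2 = delta_d^2 + delta_p^2``.
    """

    method: GCMethod
    delta_t: float
    delta_d: float | None = None
    delta_p: float | None = None
    delta_h: float | None = None

    @property
    def delta_v(self) -> float | None:
        if self.delta_d is None:
            return None
        return math.hypot(self.delta_d, self.delta_p)

    @property
    def has_components(self) -> bool:
        return self.delta_d is not None


@dataclass(frozen=True)
class ScreenResult:
    pair: tuple[str, str]
    method: GCMethod
    delta_delta_t: float  # signed, API - polymer, MPa^(1/2)
    R_av: float | None  # MPa^(1/2); None for Fedors (no components)
    chi_gc: float  # dimensionless, at the reference temperature used
    T_ref: float  # K
    verdict: str  # soluble | borderline | immiscible


def _sums(inv: GroupInventory, table: GroupTable, key: str) -> float:
    total = 0.0
    for g, n in inv.counts.items():
        if g not in table.rows:
            raise KeyError(f"group {g!r} absent from {table.method.value} table")
        total += n * table.rows[g][key]
    return total


def fedors_delta(inv: GroupInventory, table: GroupTable) -> SolubilityParams:
    """Total Hildebrand parameter from summed cohesive energies.

    delta_t = sqrt(sum n_i E_i / sum n_i V_i), E in J/mol, V in cm3/mol;
    1 J/cm3 = 1 MPa so the square root is directly in MPa^(1/2).
    """
    if table.method is not GCMethod.Fedors:
        raise ValueError("fedors_delta requires a Fedors table")
    E = _sums(inv, table, "E")
    V = _sums(inv, table, "V")
    if V <= 0:
        raise ValueError(f"{inv.compound}: total group volume must be positive")
    return SolubilityParams(method=GCMethod.Fedors, delta_t=math.sqrt(E / V))


def hvk_delta(inv: GroupInventory, table: GroupTable) -> SolubilityParams:
    """Hansen components by the Hoftyzer-van Krevelen combination rules.

    delta_d = sum(Fd)/sum(V); delta_p = sqrt(sum Fp^2)/sum(V);
    delta_h = sqrt(sum(Eh)/sum(V)); the polar term sums *squared* group
    contributions before the square root.  Serves the JB method with a JB
    coefficient table.
    """
    if table.method not in (GCMethod.HVK, GCMethod.JB):
        raise ValueError("hvk_delta requires an HVK or JB table")
    V = _sums(inv, table, "V")
    if V <= 0:
        raise ValueError(f"{inv.compound}: total group volume must be positive")
    Fd = _sums(inv, table, "Fd")
    Fp2 = sum(n * (table.rows[g]["Fp"] ** 2) for g, n in inv.counts.items())
    Eh = _sums(inv, table, "Eh")
    dd = Fd / V
    dp = math.sqrt(Fp2) / V
    dh = math.sqrt(Eh / V)
    return SolubilityParams(
        method=table.method,
        delta_d=dd,
        delta_p=dp,
        delta_h=dh,
        delta_t=math.sqrt(dd * dd + dp * dp + dh * dh),
    )


def compute_delta(inv: GroupInventory, table: GroupTable) -> SolubilityParams:
    """Dispatch to the calculator matching the table's method."""
    if table.method is GCMethod.Fedors:
        return fedors_delta(inv, table)
    return hvk_delta(inv, table)


def bagley_distance(api: SolubilityParams, poly: SolubilityParams) -> float:
    """Distance on the Bagley plane (delta_v vs delta_h), factor 4 on delta_v."""
    if api.method != poly.method:
        raise ValueError("Bagley distance requires parameters from the same method")
    if not (api.has_components and poly.has_components):
        raise ValueError("Bagley distance needs Hansen components (not Fedors)")
    return math.sqrt(
        4.0 * (poly.delta_v - api.delta_v) ** 2 + (poly.delta_h - api.delta_h) ** 2
    )


def chi_from_delta(api: SolubilityParams, poly: SolubilityParams, T: float,
                   V0: float) -> float:
    """Interaction parameter from total solubility parameters.

    chi = V0 * (delta_API - delta_poly)^2 / (R T), dimensionless, with V0
    the lattice-site molar volume in cm3/mol and delta in MPa^(1/2)
    (1 MPa^(1/2) squared = 1e6 J/m3; V0 in m3/mol = V0[cm3/mol] * 1e-6, so
    the two 1e6 factors cancel into J/mol).
    """
    if not (T > 0 and V0 > 0):
        raise ValueError("T and V0 must be positive")
    ddelta = api.delta_t - poly.delta_t
    return V0 * ddelta * ddelta / (R * T)


def screen_pair(api_inv: GroupInventory, poly_inv: GroupInventory,
                table: GroupTable, api: CompoundThermo | None = None,
                T_ref: float = 298.15, V0: float | None = None,
                api_name: str | None = None,
                poly_name: str | None = None) -> ScreenResult:
    """Screen one drug-polymer pair under one group-contribution method.

    ``V0`` defaults to the API molar volume Mw/rho (the Flory-Huggins
    lattice site is conventionally sized by the smaller molecule); supply
    either ``api`` (a :class:`CompoundThermo`) or an explicit ``V0``.
    """
    dp_api = compute_delta(api_inv, table)
    dp_poly = compute_delta(poly_inv, table)
    if V0 is None:
        if api is None:
            raise ValueError("supply api CompoundThermo or explicit V0")
        V0 = api.molar_volume
    dd = dp_api.delta_t - dp_poly.delta_t
    if abs(dd) < SOLUBLE_THRESHOLD:
        verdict = "soluble"
    elif abs(dd) <= IMMISCIBLE_THRESHOLD:
        verdict = "borderline"
    else:
        verdict = "immiscible"
    return ScreenResult(
        pair=(api_name or api_inv.compound, poly_name or poly_inv.compound),
        method=table.method,
        delta_delta_t=dd,
        R_av=bagley_distance(dp_api, dp_poly) if dp_api.has_components else None,
        chi_gc=chi_from_delta(dp_api, dp_poly, T_ref, V0),
        T_ref=T_ref,
        verdict=verdict,
    )


# ---------------------------------------------------------------------------
# I/O

def _data_path(name: str) -> Path:
    return Path(resources.files("asdkit").joinpath("data", name))


def load_group_table(method: GCMethod | str, path: str | Path | None = None) -> GroupTable:
    """Load a coefficient table (bundled illustrative one if no path given)."""
    method = GCMethod(method)
    if path is None:
        path = _data_path(f"groups_{method.value.lower()}.csv")
    df = pd.read_csv(path)
    missing = {"group", "E", "Fd", "Fp", "Eh", "V"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    rows: dict[str, dict[str, float]] = {}
    for _, r in df.iterrows():
        rows[str(r["group"])] = {
            k: float(r[k]) for k in ("E", "Fd", "Fp", "Eh", "V") if pd.notna(r[k])
        }
    return GroupTable(method=method, rows=rows, source=str(path))


def load_inventory(compound: str, path: str | Path | None = None) -> GroupInventory:
    """Load a per-compound group inventory (bundled illustrative if no path)."""
    if path is None:
        path = _data_path(f"inventory_{compound}.csv")
    df = pd.read_csv(path)
    if {"group", "count"} - set(df.columns):
        raise ValueError(f"{path}: needs columns group, count")
    return GroupInventory(
        compound=compound,
        counts={str(r["group"]): float(r["count"]) for _, r in df.iterrows()},
    )
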