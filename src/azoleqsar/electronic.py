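"""Electronic descriptors from tabulated quantum-chemistry output.

The pipeline never runs a quantum-chemistry engine; it consumes frontier
orbital energies and atomic partial charges computed elsewhere (semi-empirical
PM7, Hartree–Fock, B3LYP) and turns them into conceptual-DFT reactivity
descriptors:

* electronegativity  χ = [(−E_HOMO) + (−E_LUMO)] / 2
* hardness           η = E_LUMO − E_HOMO   (no ½ factor)
* electrophilicity   ω = χ² / (2η)

plus electron-correlation differences D_CORR = D_B3LYP − D_HF and the maximum
positive partial charge on a heavy atom (Qmax+).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DegenerateGapError, NoPositiveCenterError, UnitsError

METHODS = ("PM7", "HF", "B3LYP")
UNITS = ("eV", "hartree")


@dataclass(frozen=True)
class OrbitalEnergyRecord:
    """Frontier orbital energies of one compound from one method.

    ``e_homonl`` is the HOMO−1 ("next level") energy, ``e_lumonl`` the LUMO+1.
    All four energies share the ``units`` tag; no implicit conversion happens
    anywhere in the package.
    """

    compound_id: str
    method: str
    units: str
    e_homo: float
    e_lumo: float
    e_homonl: float
    e_lumonl: float

    def __post_init__(self):
        if self.method not in METHODS:
            raise UnitsError(f"unknown method tag {self.method!r}; expected {METHODS}")
        if self.units not in UNITS:
            raise UnitsError(f"unknown units tag {self.units!r}; expected {UNITS}")
        if self.e_homo > self.e_lumo:
            raise ValueError(
                f"{self.compound_id}: E_HOMO ({self.e_homo}) > E_LUMO ({self.e_lumo})"
            )
        if self.e_homonl > self.e_homo:
            raise ValueError(
                f"{self.compound_id}: E_HOMO-1 ({self.e_homonl}) > E_HOMO ({self.e_homo})"
            )


@dataclass
class ChargeTable:
    """Per-atom partial charges (elementary charge units) of one compound."""

    compound_id: str
    charges: list[tuple[int, str, float]] = field(default_factory=list)

    def total_charge(self) -> float:
        return sum(q for _, _, q in self.charges)


def conceptual_dft(rec: OrbitalEnergyRecord) -> tuple[float, float, float]:
    """Electronegativity χ, hardness η and electrophilicity ω of a record.

    Returned in the record's energy units (ω is energy-dimensioned under the
    χ²/2η convention).  Raises :class:`DegenerateGapError` when the HOMO–LUMO
    gap vanishes.
    """
    eta = rec.e_lumo - rec.e_homo
    if eta == 0:
        raise DegenerateGapError(
            f"{rec.compound_id}: degenerate HOMO/LUMO at {rec.e_homo} {rec.units}"
        )
    chi = ((-rec.e_homo) + (-rec.e_lumo)) / 2.0
    omega = chi * chi / (2.0 * eta)
    return chi, eta, omega


def corr_descriptor(d_b3lyp: float, d_hf: float,
                    units_b3lyp: str | None = None,
                    units_hf: str | None = None) -> float:
    """Electron-correlation descriptor D_CORR = D_B3LYP − D_HF.

    When unit tags are given they must agree; mixing eV with hartree raises.
    """
    if units_b3lyp is not None or units_hf is not None:
        if units_b3lyp != units_hf:
            raise UnitsError(
                f"unit mismatch: B3LYP in {units_b3lyp!r}, HF in {units_hf!r}"
            )
    return d_b3lyp - d_hf


def qmax_positive(table: ChargeTable) -> float:
    """Maximum positive partial charge on a non-hydrogen atom (Qmax+).

    Raises :class:`NoPositiveCenterError` when no heavy atom is positive —
    silently returning 0 would feed a fake neutral center into the agonist
    model.
    """
    heavy = [q for _, sym, q in table.charges if sym != "H"]
    if not heavy:
        raise NoPositiveCenterError(f"{table.compound_id}: empty charge table")
    qmax = max(heavy)
    if qmax <= 0:
        raise NoPositiveCenterError(
            f"{table.compound_id}: no positive non-hydrogen center (max {qmax:+.3f})"
        )
    return qmax


def read_orbital_csv(path: str | Path) -> list[OrbitalEnergyRecord]:
    """Read orbital-energy records from CSV with columns
    ``id, method, units, E_HOMO, E_HOMONL, E_LUMO, E_LUMONL``."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            OrbitalEnergyRecord(
                compound_id=str(row["id"]),
                method=str(row["method"]),
                units=str(row["units"]),
                e_homo=float(row["E_HOMO"]),
                e_homonl=float(row["E_HOMONL"]),
                e_lumo=float(row["E_LUMO"]),
                e_lumonl=float(row["E_LUMONL"]),
            )
        )
    return records


def read_charge_csv(path: str | Path, tol: float = 1e-3) -> list[ChargeTable]:
    """Read charge tables from CSV (``id, atom_index, element, charge``); each
    compound's charges must sum to an integer formal charge within ``tol``."""
    df = pd.read_csv(path)
    tables = []
    for cid, grp in df.groupby("id", sort=False):
        table = ChargeTable(
            compound_id=str(cid),
            charges=[
                (int(r["atom_index"]), str(r["element"]), float(r["charge"]))
                for _, r in grp.iterrows()
            ],
        )
        total = table.total_charge()
        if abs(total - round(total)) > tol:
            raise ValueError(
                f"{cid}: charges sum to {total:.4f}, not an integer within {tol}"
            )
        tables.append(table)
    return tables
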