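"""Synthetic data generators for end-to-end testing without external downloads.

Three generators emulate the statistical structure of the study data:

* descriptor matrices with controllable inter-column correlation and a planted
  linear model (for regression/validation recovery tests);
* azole SMILES libraries with planted structural alerts and class labels
  (emulating the 78-compound active set: default 36 agonists / 42 antagonists);
* orbital-energy and partial-charge tables with realistic frontier-energy
  ranges (semi-empirical LUMOs of active azoles fall around −1.65..−0.34 eV).

Every generator returns a :class:`SyntheticLedger` carrying the seed, the
parameters and the planted ground truth; identical seeds give identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import parse_smiles
from .electronic import ChargeTable, OrbitalEnergyRecord
from .models import DescriptorVector, ModelSpec, predict


@dataclass
class SyntheticLedger:
    """Record of how a synthetic artifact was generated."""

    seed: int
    generator: str
    params: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)


def gen_descriptor_matrix(n: int, p: int, rho: float = 0.0, seed: int = 0,
                          names: list[str] | None = None,
                          loc: np.ndarray | float = 0.0,
                          scale: np.ndarray | float = 1.0,
                          ) -> tuple[pd.DataFrame, SyntheticLedger]:
    """Gaussian descriptor matrix with equicorrelated columns.

    Columns share pairwise correlation ``rho`` (feasible for
    −1/(p−1) < rho < 1); ``loc``/``scale`` shift and scale each column to
    realistic descriptor ranges.
    """
    if n <= p or p < 1:
        raise ValueError(f"need n > p ≥ 1, got n={n}, p={p}")
    if not (-1.0 / max(p - 1, 1) < rho < 1.0):
        raise ValueError(f"correlation {rho} infeasible for p={p} columns")
    rng = np.random.default_rng(seed)
    corr = np.full((p, p), rho)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, p)) @ chol.T
    z = z * np.broadcast_to(scale, (p,)) + np.broadcast_to(loc, (p,))
    names = names or [f"x{i + 1}" for i in range(p)]
    df = pd.DataFrame(z, columns=names)
    ledger = SyntheticLedger(
        seed=seed, generator="gen_descriptor_matrix",
        params={"n": n, "p": p, "rho": rho, "names": list(names)},
    )
    return df, ledger


def gen_response(X: pd.DataFrame, model: ModelSpec, sigma: float = 0.0,
                 seed: int = 0) -> tuple[pd.Series, SyntheticLedger]:
    """Response from a planted linear model: y = predict(model, x) + N(0, σ²).

    Columns of ``X`` must cover the model's descriptor names.
    """
    missing = [n for n in model.descriptor_names if n not in X.columns]
    if missing:
        raise KeyError(f"descriptor matrix lacks model terms {missing}")
    rng = np.random.default_rng(seed)
    clean = np.array([
        predict(model, DescriptorVector(values=row.to_dict()))
        for _, row in X.iterrows()
    ])
    y = pd.Series(clean + rng.normal(0.0, sigma, size=len(X)),
                  index=X.index, name=model.activity)
    ledger = SyntheticLedger(
        seed=seed, generator="gen_response",
        params={"sigma": sigma, "model": model.name},
        truth={"intercept": model.intercept, "terms": list(model.terms)},
    )
    return y, ledger


# fragments used to assemble azole libraries; each planted alert maps to a
# head template with a {tail} slot receiving linker + azole scaffold
_AGONIST_HEADS = {
    "SA4": "OC(=O){tail}",   # carboxylic acid
    "SA8": "NC(=O){tail}",   # primary amide
}
_ANTAGONIST_HEADS = {
    "SA9": "Clc1ccc({tail})cc1",      # chlorobenzene
    "SA2": "Clc1ccc(CC{tail})cc1",    # p-ethyl chlorobenzene (tail extends CC)
}
_LINKERS = ("C", "CC", "CCC", "CCCC", "C(C)C", "CCCCC",
            "C(C)", "CC(C)", "CCC(C)", "C(C)CC", "CCCCCC", "CC(C)C")
#: imidazole/thiazole scaffolds safe for agonists (no 1,2,4-triazole, which is
#: an infinite-LR antagonist alert)
_AGONIST_SCAFFOLDS = ("n2ccnc2", "c2ncc[nH]2", "c2nccs2", "c2scnc2",
                      "n2ccnc2C", "c2nc(C)c[nH]2")
#: imidazole/1,2,4-triazole scaffolds for antagonists (no thiazole, which is an
#: infinite-LR agonist alert)
_ANTAGONIST_SCAFFOLDS = ("n2ccnc2", "c2ncc[nH]2", "n2cncn2", "n2ccnc2C",
                         "c2nc(C)c[nH]2", "n2cc(C)nc2")


def _candidates(head: str, scaffolds) -> list[str]:
    out = []
    for scaf in scaffolds:
        for link in _LINKERS:
            out.append(head.format(tail=link + scaf))
    return out


def gen_azole_library(n_agonists: int = 36, n_antagonists: int = 42,
                      planted: dict[str, str] | None = None, seed: int = 0,
                      ) -> tuple[list[tuple[str, str]], SyntheticLedger]:
    """Azole SMILES library with planted structural alerts and labels.

    Every agonist carries the planted agonist alert (default SA4, carboxylic
    acid) and every antagonist the planted antagonist alert (default SA9,
    chlorobenzene); scaffolds are imidazoles, thiazoles and 1,2,4-triazoles so
    every molecule is an azole.  Returns ``[(smiles, label), ...]`` and a
    ledger whose truth maps each SMILES to its planted alert.
    """
    planted = planted or {"agonist": "SA4", "antagonist": "SA9"}
    if planted["agonist"] not in _AGONIST_HEADS:
        raise ValueError(f"unsupported agonist alert {planted['agonist']!r}")
    if planted["antagonist"] not in _ANTAGONIST_HEADS:
        raise ValueError(f"unsupported antagonist alert {planted['antagonist']!r}")
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    for label, n_wanted, head, scaffolds in (
        ("agonist", n_agonists, _AGONIST_HEADS[planted["agonist"]],
         _AGONIST_SCAFFOLDS),
        ("antagonist", n_antagonists, _ANTAGONIST_HEADS[planted["antagonist"]],
         _ANTAGONIST_SCAFFOLDS),
    ):
        cands = _candidates(head, scaffolds)
        rng.shuffle(cands)
        seen = set()
        picked = []
        for smi in cands:
            g = parse_smiles(smi, smi)  # validates
            canon = g.canonical_smiles()
            if canon in seen:
                continue
            seen.add(canon)
            picked.append(canon)
            if len(picked) == n_wanted:
                break
        if len(picked) < n_wanted:
            raise ValueError(
                f"cannot assemble {n_wanted} unique {label}s "
                f"(only {len(picked)} available)"
            )
        for smi in picked:
            out.append((smi, label))
            truth[smi] = planted[label]
    ledger = SyntheticLedger(
        seed=seed, generator="gen_azole_library",
        params={"n_agonists": n_agonists, "n_antagonists": n_antagonists,
                "planted": dict(planted)},
        truth={"alert_by_smiles": truth},
    )
    return out, ledger


#: default frontier-energy sampling ranges per method (lo, hi)
DEFAULT_ORBITAL_RANGES = {
    "PM7": {"units": "eV", "homo": (-10.0, -8.5), "lumo": (-1.65, -0.344),
            "gap_below": (0.3, 1.5), "gap_above": (0.3, 1.5)},
    "HF": {"units": "hartree", "homo": (-0.40, -0.30), "lumo": (0.02, 0.10),
           "gap_below": (0.02, 0.08), "gap_above": (0.02, 0.08)},
    "B3LYP": {"units": "hartree", "homo": (-0.28, -0.20), "lumo": (-0.10, -0.02),
              "gap_below": (0.02, 0.08), "gap_above": (0.02, 0.08)},
}


def gen_orbital_tables(ids: list[str], seed: int = 0,
                       ranges: dict | None = None,
                       methods: tuple[str, ...] = ("PM7", "HF", "B3LYP"),
                       n_atoms: int = 15,
                       ) -> tuple[list[OrbitalEnergyRecord], list[ChargeTable],
                                  SyntheticLedger]:
    """Plausible orbital-energy records and charge tables for a compound list.

    Frontier energies are drawn within the per-method ranges (HOMO−1 below the
    HOMO, LUMO+1 above the LUMO); partial charges are centred so each table
    sums to zero.
    """
    ranges = ranges or DEFAULT_ORBITAL_RANGES
    for method in methods:
        r = ranges[method]
        if r["homo"][0] > r["homo"][1] or r["lumo"][0] > r["lumo"][1]:
            raise ValueError(f"{method}: inverted energy range")
        if r["homo"][1] > r["lumo"][0]:
            raise ValueError(f"{method}: HOMO range overlaps LUMO range")
    rng = np.random.default_rng(seed)
    records = []
    for cid in ids:
        for method in methods:
            r = ranges[method]
            homo = rng.uniform(*r["homo"])
            lumo = rng.uniform(*r["lumo"])
            records.append(OrbitalEnergyRecord(
                compound_id=cid, method=method, units=r["units"],
                e_homo=homo,
                e_homonl=homo - rng.uniform(*r["gap_below"]),
                e_lumo=lumo,
                e_lumonl=lumo + rng.uniform(*r["gap_above"]),
            ))
    elements = np.array(["C", "C", "C", "N", "O", "Cl"])
    tables = []
    for cid in ids:
        syms = rng.choice(elements, size=n_atoms)
        q = rng.normal(0.0, 0.2, size=n_atoms)
        q -= q.mean()  # neutral molecule
        tables.append(ChargeTable(
            compound_id=cid,
            charges=[(i, str(s), float(v)) for i, (s, v) in enumerate(zip(syms, q))],
        ))
    ledger = SyntheticLedger(
        seed=seed, generator="gen_orbital_tables",
        params={"ids": list(ids), "methods": list(methods)},
    )
    return records, tables, ledger
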