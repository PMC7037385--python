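"""Dataset curation: activity-unit conversion, duplicate resolution, azole
filtering and Tanimoto similarity matrices.

Activities arrive as AC50 in nanomolar; models work on the p-scale
(−log10 of the molar concentration), so p = 9 − log10(AC50[nM]).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, MACCSkeys

from .chem import MolecularGraph, azole_class, parse_smiles

#: duplicate groups whose AC50 spread exceeds this ratio are rejected
DUPLICATE_RATIO = 3.0


@dataclass(frozen=True)
class ActivityRecord:
    """One assay outcome: structure, AC50 (nM) and/or p-activity, class."""

    id: str
    smiles: str
    activity_type: str  # "agonist", "antagonist" or "inactive"
    ac50_nm: float | None = None
    p_activity: float | None = None
    azole: str = ""


def to_p_activity(ac50_nm: float) -> float:
    """Convert AC50 in nM to the p-scale: −log10(AC50) + 9."""
    if ac50_nm <= 0:
        raise ValueError(f"AC50 must be positive, got {ac50_nm}")
    return 9.0 - math.log10(ac50_nm)


def from_p_activity(p: float) -> float:
    """Inverse conversion: AC50[nM] = 10^(9 − p)."""
    return 10.0 ** (9.0 - p)


@dataclass
class Resolution:
    """Outcome of merging duplicate records of one structure."""

    kept: ActivityRecord | None
    rejected: bool
    reason: str = ""


def resolve_duplicates(records: list[ActivityRecord],
                       geometric_mean: bool = False) -> Resolution:
    """Merge records sharing one canonical structure.

    Keeps a single record with the mean AC50 when the activity spread
    (max/min) is within 1:3; rejects wider spreads and groups mixing agonist
    with antagonist outcomes.  The mean is arithmetic on the AC50 scale by
    default (``geometric_mean=True`` switches to the geometric mean).
    """
    if not records:
        raise ValueError("empty duplicate group")
    if len(records) == 1:
        return Resolution(kept=records[0], rejected=False)
    types = {r.activity_type for r in records}
    if len(types) > 1:
        return Resolution(
            kept=None, rejected=True,
            reason=f"conflicting activity types {sorted(types)}",
        )
    values = [r.ac50_nm for r in records]
    if any(v is None or v <= 0 for v in values):
        return Resolution(kept=None, rejected=True, reason="missing AC50 value")
    ratio = max(values) / min(values)
    if ratio > DUPLICATE_RATIO:
        return Resolution(
            kept=None, rejected=True,
            reason=f"activity range 1:{ratio:.1f} exceeds 1:{DUPLICATE_RATIO:g}",
        )
    if geometric_mean:
        mean = float(np.exp(np.mean(np.log(values))))
    else:
        mean = float(np.mean(values))
    kept = replace(records[0], ac50_nm=mean, p_activity=to_p_activity(mean))
    return Resolution(kept=kept, rejected=False)


def curate(records: list[ActivityRecord],
           geometric_mean: bool = False) -> tuple[list[ActivityRecord], pd.DataFrame]:
    """Canonicalize structures, merge duplicates, and log rejections.

    Returns the curated records plus a rejection log (id, reason).
    """
    groups: dict[str, list[ActivityRecord]] = {}
    rejections = []
    for rec in records:
        try:
            g = parse_smiles(rec.smiles, rec.id)
        except Exception as exc:
            rejections.append((rec.id, str(exc)))
            continue
        groups.setdefault(g.canonical_smiles(), []).append(rec)
    kept = []
    for canon, grp in groups.items():
        res = resolve_duplicates(grp, geometric_mean=geometric_mean)
        if res.rejected:
            rejections.append(("|".join(r.id for r in grp), res.reason))
        else:
            kept.append(replace(res.kept, smiles=canon))
    log = pd.DataFrame(rejections, columns=["id", "reason"])
    return kept, log


def filter_azoles(records: list[ActivityRecord]) -> tuple[list[ActivityRecord], pd.DataFrame]:
    """Keep azoles only; returns the subset and a class × activity count table."""
    kept = []
    counts: dict[tuple[str, str], int] = {}
    for rec in records:
        g = parse_smiles(rec.smiles, rec.id)
        cls, _flag = azole_class(g)
        if cls == "none":
            continue
        kept.append(replace(rec, azole=cls))
        counts[(cls, rec.activity_type)] = counts.get((cls, rec.activity_type), 0) + 1
    table = pd.Series(counts, dtype=int).unstack(fill_value=0) if counts else pd.DataFrame()
    return kept, table


def _fingerprint(mol: Chem.Mol, scheme: str):
    if scheme == "maccs":
        return MACCSkeys.GenMACCSKeys(mol)
    if scheme == "morgan":
        gen = AllChem.GetMorganGenerator(radius=2, fpSize=2048)
        return gen.GetFingerprint(mol)
    if scheme == "rdkit":
        return Chem.RDKFingerprint(mol)
    raise ValueError(f"unknown fingerprint scheme {scheme!r}")


def tanimoto_matrix(graphs: list[MolecularGraph], scheme: str = "maccs") -> np.ndarray:
    """Pairwise Tanimoto similarity T = |A∩B|/|A∪B| on binary fingerprints.

    Symmetric with unit diagonal.  An empty fingerprint is defined as
    similarity 0 to everything (with a warning) rather than NaN.
    """
    if len(graphs) < 2:
        raise ValueError("need at least 2 molecules")
    fps = [_fingerprint(g.mol, scheme) for g in graphs]
    n = len(fps)
    sizes = [fp.GetNumOnBits() for fp in fps]
    if any(s == 0 for s in sizes):
        warnings.warn("empty fingerprint; similarities set to 0", stacklevel=2)
    t = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if sizes[i] == 0 or sizes[j] == 0:
                sim = 0.0
            else:
                a = set(fps[i].GetOnBits())
                b = set(fps[j].GetOnBits())
                sim = len(a & b) / len(a | b)
            t[i, j] = t[j, i] = sim
    return t
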