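"""Molecular graphs, ring perception, SMARTS matching and azole classification.

Everything downstream (topological descriptors, alerts, curation) works on the
hydrogen-suppressed molecular graph.  RDKit does the heavy lifting — parsing,
aromaticity perception, SSSR, substructure matching — and :class:`MolecularGraph`
exposes the graph-level view (atoms, bonds, distances) the descriptor code needs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import MixtureError, SmartsPatternError, SmilesParseError

RDLogger.DisableLog("rdApp.*")

AZOLE_CLASSES = ("none", "monoazole", "diazole", "triazole", "tetrazole")


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed labeled molecular graph.

    ``atoms`` holds ``(element, formal_charge, aromatic, n_hydrogens)`` tuples and
    ``bonds`` holds ``(i, j, order)`` with ``order`` in ``{1, 2, 3, 1.5}`` (1.5 for
    aromatic bonds).  The backing RDKit molecule is kept for substructure work.
    """

    atoms: list[tuple[str, int, bool, int]]
    bonds: list[tuple[int, int, float]]
    id: str = ""
    mol: Chem.Mol = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


@dataclass
class RingInfo:
    """SSSR rings plus the partition of ring atoms into ring systems.

    A ring system is a maximal set of SSSR rings connected through shared atoms,
    so fused and spiro rings fall in one system while rings joined only by an
    acyclic bond are distinct systems.
    """

    sssr_rings: list[tuple[int, ...]]
    ring_atoms: set[int]
    ring_bonds: set[tuple[int, int]]
    ring_systems: list[set[int]]

    @property
    def n_rings(self) -> int:
        return len(self.sssr_rings)

    @property
    def n_systems(self) -> int:
        return len(self.ring_systems)


def parse_smiles(text: str, id: str = "") -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Raises
    ------
    SmilesParseError
        If RDKit cannot parse the string.
    MixtureError
        If the structure is disconnected (mixtures are rejected upstream of
        descriptor computation; salts must be stripped first).
    """
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES for {id or 'input'!r}: {text!r}")
    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        raise MixtureError(
            f"disconnected structure (mixture) for {id or 'input'!r}: {text!r}"
        )
    atoms = [
        (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic(), a.GetTotalNumHs())
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        if b.GetIsAromatic():
            order = 1.5
        else:
            order = float(b.GetBondTypeAsDouble())
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return MolecularGraph(atoms=atoms, bonds=bonds, id=id, mol=mol)


def strip_salts(text: str) -> str:
    """Keep the largest covalent fragment of a dotted SMILES (salt stripping)."""
    parts = text.split(".")
    if len(parts) == 1:
        return text
    sizes = []
    for p in parts:
        m = Chem.MolFromSmiles(p)
        sizes.append(m.GetNumAtoms() if m is not None else -1)
    return parts[int(np.argmax(sizes))]


def ring_info(g: MolecularGraph) -> RingInfo:
    """SSSR rings, ring atom/bond sets and the fused/spiro ring-system partition."""
    ri = g.mol.GetRingInfo()
    rings = [tuple(r) for r in ri.AtomRings()]
    ring_atoms = {a for r in rings for a in r}
    ring_bonds = set()
    for bond_ring in ri.BondRings():
        for bidx in bond_ring:
            b = g.mol.GetBondWithIdx(bidx)
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            ring_bonds.add((min(i, j), max(i, j)))
    # union-find over rings sharing at least one atom
    parent = list(range(len(rings)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(len(rings)):
        for b in range(a + 1, len(rings)):
            if set(rings[a]) & set(rings[b]):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    systems: dict[int, set[int]] = {}
    for idx, r in enumerate(rings):
        systems.setdefault(find(idx), set()).update(r)
    return RingInfo(
        sssr_rings=rings,
        ring_atoms=ring_atoms,
        ring_bonds=ring_bonds,
        ring_systems=list(systems.values()),
    )


def topo_distances(g: MolecularGraph) -> np.ndarray:
    """Matrix of shortest bond-count path lengths between heavy atoms."""
    d = Chem.GetDistanceMatrix(g.mol)
    # RDKit marks unreachable pairs with a large sentinel (1e8)
    if np.isinf(d).any() or d.max() >= 1e7:
        raise MixtureError(f"disconnected graph for {g.id!r}")
    return d.astype(int)


def match_smarts(g: MolecularGraph, pattern: str) -> tuple[bool, int]:
    """Substructure presence and number of distinct matches of a SMARTS pattern."""
    patt = Chem.MolFromSmarts(pattern)
    if patt is None:
        raise SmartsPatternError(f"invalid SMARTS: {pattern!r}")
    matches = g.mol.GetSubstructMatches(patt, uniquify=True)
    return (len(matches) > 0, len(matches))


def azole_class(g: MolecularGraph) -> tuple[str, bool]:
    """Azole taxonomy of a molecule: nitrogen count in 5-membered aromatic rings.

    Scans all 5-membered aromatic rings, takes the maximum ring nitrogen count
    (1 → monoazole … 4 → tetrazole) and flags thiazole/oxazole when a qualifying
    ring also contains sulfur or oxygen.  Molecules without such a ring return
    ``("none", False)``.
    """
    info = ring_info(g)
    best_n = 0
    flag = False
    for ring in info.sssr_rings:
        if len(ring) != 5:
            continue
        syms = [g.atoms[i][0] for i in ring]
        aromatic = all(g.atoms[i][2] for i in ring)
        if not aromatic:
            continue
        n_count = syms.count("N")
        if n_count == 0:
            continue
        if n_count > best_n:
            best_n = n_count
            flag = "S" in syms or "O" in syms
        elif n_count == best_n and ("S" in syms or "O" in syms):
            flag = True
    names = {1: "monoazole", 2: "diazole", 3: "triazole", 4: "tetrazole"}
    return (names.get(best_n, "none"), flag)


def read_smiles_file(path: str | Path) -> list[MolecularGraph]:
    """Read a ``.smi`` file (``SMILES [whitespace] id`` per line) or a CSV with a
    ``smiles`` column (optional ``id`` column)."""
    path = Path(path)
    graphs = []
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "smiles" not in cols:
            raise SmilesParseError(f"{path}: no 'smiles' column")
        idcol = cols.get("id")
        for k, row in df.iterrows():
            ident = str(row[idcol]) if idcol else f"mol{k}"
            graphs.append(parse_smiles(str(row[cols["smiles"]]), ident))
    else:
        for k, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            ident = parts[1].strip() if len(parts) > 1 else f"mol{k}"
            graphs.append(parse_smiles(smi, ident))
    return graphs
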