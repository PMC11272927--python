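"""Pharmacophore pair counts, Galvez charge indices and ring-count descriptors.

* CATS2D: counts of unordered pharmacophore-point pairs (donor, acceptor,
  positive, negative, lipophilic, aromatic) at topological distances 0-9 —
  21 pairs * 10 lags = 210 descriptors.
* Galvez topological charge indices GGI1-10 / JGI1-10 / JGT10 — 21.
* Ring counts by size (3-12) and character (any / aromatic / heteroatomic /
  saturated / fused) over the SSSR — 50.
"""

from __future__ import annotations

from itertools import combinations_with_replacement

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdmolops
from rdkit.Chem.Lipinski import HAcceptorSmarts, HDonorSmarts

CATS_TYPES = ("D", "A", "P", "N", "L", "R")
CATS_MAX_DIST = 9

_CATS_PATTERNS: dict[str, list[Chem.Mol]] = {
    "D": [HDonorSmarts],
    "A": [HAcceptorSmarts],
    "P": [Chem.MolFromSmarts("[*+1,*+2,*+3]"),
          Chem.MolFromSmarts("[NX3;H2;!$(NC=O);!$(N~[!#6])]")],
    "N": [Chem.MolFromSmarts("[*-1,*-2,*-3]"),
          Chem.MolFromSmarts("[OX2H][CX3]=[OX1]"),
          Chem.MolFromSmarts("[OX2H][SX4](=O)=O"),
          Chem.MolFromSmarts("[OX2H][PX4]=O")],
    "L": [Chem.MolFromSmarts("[C;!$(C~[#7,#8,#9,#15,#16,Cl,Br,I])]"),
          Chem.MolFromSmarts("[Cl,Br,I]"),
          Chem.MolFromSmarts("[SX2;$(S(C)C)]")],
    "R": [Chem.MolFromSmarts("[a]")],
}

CATS_PAIRS = list(combinations_with_replacement(CATS_TYPES, 2))


def cats2d_names() -> list[str]:
    return [f"CATS2D_{a}{b}_{d}" for a, b in CATS_PAIRS
            for d in range(CATS_MAX_DIST + 1)]


def cats2d(mol: Chem.Mol) -> dict[str, float]:
    n = mol.GetNumAtoms()
    member = {t: np.zeros(n, dtype=bool) for t in CATS_TYPES}
    for t, patterns in _CATS_PATTERNS.items():
        for patt in patterns:
            for match in mol.GetSubstructMatches(patt):
                member[t][match[0]] = True
    dist = rdmolops.GetDistanceMatrix(mol) if n else np.zeros((0, 0))

    values: dict[str, float] = {}
    for a, b in CATS_PAIRS:
        ma, mb = member[a], member[b]
        for d in range(CATS_MAX_DIST + 1):
            if d == 0:
                count = int(np.sum(ma & mb))
            else:
                pair_mask = np.outer(ma, mb) | np.outer(mb, ma)
                count = int(np.sum(np.triu(pair_mask & (dist == d), k=1)))
            values[f"CATS2D_{a}{b}_{d}"] = float(count)
    return values


# -- Galvez topological charge indices --------------------------------------

GALVEZ_MAX_ORDER = 10


def galvez_names() -> list[str]:
    return ([f"GGI{k}" for k in range(1, GALVEZ_MAX_ORDER + 1)]
            + [f"JGI{k}" for k in range(1, GALVEZ_MAX_ORDER + 1)]
            + ["JGT10"])


def galvez(mol: Chem.Mol) -> dict[str, float]:
    """Charge-transfer indices from M = A · D*, with D* the inverse-square
    topological distance matrix; GGI_k sums |m_ij − m_ji| over pairs at
    distance k, JGI_k is the per-edge mean GGI_k / (n − 1)."""
    n = mol.GetNumAtoms()
    names = galvez_names()
    if n < 2:
        return {name: float("nan") for name in names}
    adj = rdmolops.GetAdjacencyMatrix(mol).astype(float)
    dist = rdmolops.GetDistanceMatrix(mol).copy()
    dist[dist > n] = 0.0
    with np.errstate(divide="ignore"):
        dstar = np.where(dist > 0, 1.0 / dist ** 2, 0.0)
    m = adj @ dstar
    ct = m - m.T

    values: dict[str, float] = {}
    total = 0.0
    for k in range(1, GALVEZ_MAX_ORDER + 1):
        mask = np.triu(dist == k, k=1)
        ggi = float(np.sum(np.abs(ct)[mask]))
        jgi = ggi / (n - 1)
        values[f"GGI{k}"] = ggi
        values[f"JGI{k}"] = jgi
        total += jgi
    values["JGT10"] = total
    return values


# -- classical distance-matrix topological indices ---------------------------

TOPOINDEX_NAMES = ("Diameter", "Radius", "PetitjeanIndex", "ECCEN",
                   "WPATH", "AWPATH", "WPOL", "MeanECC")


def topoindex(mol: Chem.Mol) -> dict[str, float]:
    """Eccentricity- and Wiener-type indices of the topological distance matrix:
    graph diameter/radius, Petitjean shape index, eccentric connectivity,
    Wiener path sum and its pair mean, polarity number (pairs at distance 3),
    and mean eccentricity."""
    n = mol.GetNumAtoms()
    if n == 0:
        return {name: float("nan") for name in TOPOINDEX_NAMES}
    dist = rdmolops.GetDistanceMatrix(mol).copy()
    dist[dist > n] = 0.0
    ecc = dist.max(axis=1)
    diameter, radius = float(ecc.max()), float(ecc.min())
    degrees = np.array([a.GetDegree() for a in mol.GetAtoms()], dtype=float)
    n_pairs = n * (n - 1) / 2
    wiener = float(np.sum(np.triu(dist, k=1)))
    return {
        "Diameter": diameter,
        "Radius": radius,
        "PetitjeanIndex": (diameter - radius) / radius if radius else 0.0,
        "ECCEN": float(np.sum(degrees * ecc)),
        "WPATH": wiener,
        "AWPATH": wiener / n_pairs if n_pairs else 0.0,
        "WPOL": float(np.sum(np.triu(dist == 3, k=1))),
        "MeanECC": float(ecc.mean()),
    }


# -- ring counts -------------------------------------------------------------

RING_SIZES = range(3, 13)
RING_KINDS = ("", "A", "H", "s", "F")  # any, aromatic, hetero, saturated, fused


def ring_names() -> list[str]:
    return [f"n{size}{kind}Ring" for kind in RING_KINDS for size in RING_SIZES]


def ring_counts(mol: Chem.Mol) -> dict[str, float]:
    info = mol.GetRingInfo()
    atom_rings = info.AtomRings()
    bond_rings = [frozenset(r) for r in info.BondRings()]
    values = {name: 0.0 for name in ring_names()}
    for ring_atoms, ring_bonds in zip(atom_rings, bond_rings):
        size = len(ring_atoms)
        if size not in RING_SIZES:
            continue
        atoms = [mol.GetAtomWithIdx(i) for i in ring_atoms]
        bonds = [mol.GetBondWithIdx(i) for i in ring_bonds]
        aromatic = all(a.GetIsAromatic() for a in atoms)
        hetero = any(a.GetAtomicNum() != 6 for a in atoms)
        saturated = all(b.GetBondType() == Chem.BondType.SINGLE for b in bonds)
        fused = any(ring_bonds & other for other in bond_rings
                    if other is not ring_bonds and len(ring_bonds & other) > 0)
        values[f"n{size}Ring"] += 1
        if aromatic:
            values[f"n{size}ARing"] += 1
        if hetero:
            values[f"n{size}HRing"] += 1
        if saturated:
            values[f"n{size}sRing"] += 1
        if fused:
            values[f"n{size}FRing"] += 1
    return values
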