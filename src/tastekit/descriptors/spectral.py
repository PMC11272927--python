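"""Eigenspectrum descriptors of molecular graph matrices.

Twelve spectral statistics (SpAbs, SpMax, SpDiam, SpAD, SpMAD, LogEE,
VE1-3, VR1-3) over the adjacency (A), Laplacian (L) and topological distance
(D) matrices, plus the Barysz weighted distance matrix (Dz) under eight
atomic weightings — 12 * (3 + 8) = 132 descriptors.

SpDiam is the eigenvalue range (largest minus smallest); for a single heavy
atom the adjacency matrix is 1x1 zero, so SpDiam_A = 0.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdmolops
from scipy.sparse.csgraph import shortest_path
from scipy.special import logsumexp

from .atomprops import _PT, _vdw_volume, ALLRED_ROCHOW_EN, IONIZATION_EV, \
    PAULING_EN, POLARIZABILITY, SANDERSON_EN

STAT_NAMES = ("SpAbs", "SpMax", "SpDiam", "SpAD", "SpMAD", "LogEE",
              "VE1", "VE2", "VE3", "VR1", "VR2", "VR3")

#: Barysz weightings: atomic number, mass, vdW volume, three electronegativity
#: scales, polarizability, ionization energy
BARYSZ_CODES = ("Z", "m", "v", "se", "pe", "are", "p", "i")

_ELEMENT_TABLES = {
    "Z": lambda z: float(z),
    "m": lambda z: _PT.GetAtomicWeight(z),
    "v": _vdw_volume,
    "se": lambda z: SANDERSON_EN.get(z, float("nan")),
    "pe": lambda z: PAULING_EN.get(z, float("nan")),
    "are": lambda z: ALLRED_ROCHOW_EN.get(z, float("nan")),
    "p": lambda z: POLARIZABILITY.get(z, float("nan")),
    "i": lambda z: IONIZATION_EV.get(z, float("nan")),
}


def descriptor_names() -> list[str]:
    suffixes = ["A", "L", "D"] + [f"Dz{w}" for w in BARYSZ_CODES]
    return [f"{stat}_{suf}" for suf in suffixes for stat in STAT_NAMES]


def spectral_stats(matrix: np.ndarray,
                   edges: list[tuple[int, int]]) -> dict[str, float]:
    """The twelve eigenspectrum statistics of a symmetric matrix.

    ``edges`` (graph bonds) are needed for the Randic-like VR statistics.
    """
    n = matrix.shape[0]
    if n == 0 or np.isnan(matrix).any():
        return {s: float("nan") for s in STAT_NAMES}
    eigvals, eigvecs = np.linalg.eigh(matrix)
    lead = np.abs(eigvecs[:, -1])

    out: dict[str, float] = {}
    out["SpAbs"] = float(np.sum(np.abs(eigvals)))
    out["SpMax"] = float(eigvals[-1])
    out["SpDiam"] = float(eigvals[-1] - eigvals[0])
    out["SpAD"] = float(np.sum(np.abs(eigvals - eigvals.mean())))
    out["SpMAD"] = out["SpAD"] / n
    out["LogEE"] = float(logsumexp(eigvals))
    ve1 = float(np.sum(lead))
    out["VE1"] = ve1
    out["VE2"] = ve1 / n
    out["VE3"] = float(np.log(0.1 * n * ve1)) if ve1 > 0 else float("nan")
    if edges:
        prods = np.array([lead[i] * lead[j] for i, j in edges])
        if (prods > 0).all():
            vr1 = float(np.sum(prods ** -0.5))
            out["VR1"] = vr1
            out["VR2"] = vr1 / n
            out["VR3"] = float(np.log(0.1 * n * vr1)) if vr1 > 0 else float("nan")
        else:
            out["VR1"] = out["VR2"] = out["VR3"] = float("nan")
    else:
        out["VR1"] = out["VR2"] = out["VR3"] = float("nan")
    return out


def barysz_matrix(mol: Chem.Mol, code: str) -> np.ndarray:
    """Barysz weighted distance matrix relative to carbon.

    Edge weight of bond (i,j) with order b: (w_C^2) / (b * w_i * w_j);
    off-diagonal entries are minimal path-weight sums, the diagonal is
    1 - w_C / w_i.
    """
    table = _ELEMENT_TABLES[code]
    w_c = table(6)
    n = mol.GetNumAtoms()
    w = np.array([table(a.GetAtomicNum()) for a in mol.GetAtoms()])
    if np.isnan(w).any() or (w == 0).any():
        return np.full((n, n), np.nan)
    adj = np.zeros((n, n))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        weight = w_c ** 2 / (bond.GetBondTypeAsDouble() * w[i] * w[j])
        adj[i, j] = adj[j, i] = weight
    if n == 1:
        dz = np.zeros((1, 1))
    else:
        dz = shortest_path(adj, method="D", directed=False)
        dz[~np.isfinite(dz)] = 0.0  # disconnected fragments: no path term
    np.fill_diagonal(dz, 1.0 - w_c / w)
    return dz


def compute(mol: Chem.Mol) -> dict[str, float]:
    n = mol.GetNumAtoms()
    edges = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    adj = rdmolops.GetAdjacencyMatrix(mol).astype(float)
    lap = np.diag(adj.sum(axis=1)) - adj
    dist = rdmolops.GetDistanceMatrix(mol).copy()
    dist[dist > n] = 0.0  # rdkit marks disconnected pairs with a huge sentinel
    matrices = {"A": adj, "L": lap, "D": dist}
    for code in BARYSZ_CODES:
        matrices[f"Dz{code}"] = barysz_matrix(mol, code)

    values: dict[str, float] = {}
    for suf, matrix in matrices.items():
        stats = spectral_stats(matrix, edges)
        for stat in STAT_NAMES:
            values[f"{stat}_{suf}"] = stats[stat]
    return values
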