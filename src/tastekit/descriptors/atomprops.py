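"""Per-atom properties used as weights in autocorrelation and Barysz descriptors.

All descriptors operate on the hydrogen-suppressed graph; per-atom values are
computed for heavy atoms only (Gasteiger charges fold the attached-hydrogen
contribution into the heavy atom).  Element-level constants (electronegativity
scales, polarizability, ionization energy) are standard tabulated values;
elements absent from a table yield NaN, which propagates to a missing
descriptor value rather than a silent zero.
"""

from __future__ import annotations

import math

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdPartialCharges

_PT = Chem.GetPeriodicTable()

# Pauling electronegativity
PAULING_EN = {
    1: 2.20, 3: 0.98, 4: 1.57, 5: 2.04, 6: 2.55, 7: 3.04, 8: 3.44, 9: 3.98,
    11: 0.93, 12: 1.31, 13: 1.61, 14: 1.90, 15: 2.19, 16: 2.58, 17: 3.16,
    19: 0.82, 20: 1.00, 22: 1.54, 24: 1.66, 25: 1.55, 26: 1.83, 27: 1.88,
    28: 1.91, 29: 1.90, 30: 1.65, 31: 1.81, 32: 2.01, 33: 2.18, 34: 2.55,
    35: 2.96, 37: 0.82, 38: 0.95, 42: 2.16, 47: 1.93, 48: 1.69, 50: 1.96,
    51: 2.05, 52: 2.10, 53: 2.66, 55: 0.79, 56: 0.89, 78: 2.28, 79: 2.54,
    80: 2.00, 82: 2.33, 83: 2.02,
}

# Sanderson electronegativity
SANDERSON_EN = {
    1: 2.592, 3: 0.670, 4: 1.810, 5: 2.275, 6: 2.746, 7: 3.194, 8: 3.654,
    9: 4.000, 11: 0.560, 12: 1.318, 13: 1.714, 14: 2.138, 15: 2.515,
    16: 2.957, 17: 3.475, 19: 0.445, 20: 0.946, 25: 2.07, 26: 2.20,
    27: 2.56, 28: 1.94, 29: 2.033, 30: 2.223, 31: 2.419, 32: 2.618,
    33: 2.816, 34: 3.014, 35: 3.219, 37: 0.312, 38: 0.721, 47: 1.826,
    48: 1.978, 50: 2.298, 51: 2.458, 52: 2.618, 53: 2.778, 55: 0.220,
    56: 0.651, 80: 2.195, 82: 2.291, 83: 2.342,
}

# Allred-Rochow electronegativity
ALLRED_ROCHOW_EN = {
    1: 2.20, 3: 0.97, 4: 1.47, 5: 2.01, 6: 2.50, 7: 3.07, 8: 3.50, 9: 4.10,
    11: 1.01, 12: 1.23, 13: 1.47, 14: 1.74, 15: 2.06, 16: 2.44, 17: 2.83,
    19: 0.91, 20: 1.04, 22: 1.32, 24: 1.56, 25: 1.60, 26: 1.64, 27: 1.70,
    28: 1.75, 29: 1.75, 30: 1.66, 31: 1.82, 32: 2.02, 33: 2.20, 34: 2.48,
    35: 2.74, 37: 0.89, 38: 0.99, 47: 1.42, 48: 1.46, 50: 1.72, 51: 1.82,
    52: 2.01, 53: 2.21, 55: 0.86, 56: 0.97, 80: 1.44, 82: 1.55, 83: 1.67,
}

# static dipole polarizability, Å^3
POLARIZABILITY = {
    1: 0.667, 3: 24.3, 4: 5.60, 5: 3.03, 6: 1.76, 7: 1.10, 8: 0.802,
    9: 0.557, 11: 24.1, 12: 10.6, 13: 6.8, 14: 5.38, 15: 3.63, 16: 2.90,
    17: 2.18, 19: 43.4, 20: 22.8, 25: 9.4, 26: 8.4, 27: 7.5, 28: 6.8,
    29: 6.1, 30: 7.1, 31: 8.12, 32: 6.07, 33: 4.31, 34: 3.77, 35: 3.05,
    37: 47.3, 38: 27.6, 47: 7.2, 48: 7.2, 50: 7.7, 51: 6.6, 52: 5.5,
    53: 5.35, 55: 59.4, 56: 39.7, 80: 5.7, 82: 6.8, 83: 7.4,
}

# first ionization energy, eV
IONIZATION_EV = {
    1: 13.598, 3: 5.392, 4: 9.323, 5: 8.298, 6: 11.260, 7: 14.534,
    8: 13.618, 9: 17.423, 11: 5.139, 12: 7.646, 13: 5.986, 14: 8.152,
    15: 10.487, 16: 10.360, 17: 12.968, 19: 4.341, 20: 6.113, 22: 6.828,
    24: 6.767, 25: 7.434, 26: 7.902, 27: 7.881, 28: 7.640, 29: 7.726,
    30: 9.394, 31: 5.999, 32: 7.899, 33: 9.815, 34: 9.752, 35: 11.814,
    37: 4.177, 38: 5.695, 42: 7.092, 47: 7.576, 48: 8.994, 50: 7.344,
    51: 8.608, 52: 9.010, 53: 10.451, 55: 3.894, 56: 5.212, 78: 8.959,
    79: 9.226, 80: 10.438, 82: 7.417, 83: 7.286,
}

#: weighting codes, in mordred-style order: Gasteiger charge, valence degree,
#: sigma degree, intrinsic state, atomic number, mass, vdW volume, Sanderson /
#: Pauling / Allred-Rochow electronegativity, polarizability, ionization energy
PROPERTY_CODES: tuple[str, ...] = (
    "c", "dv", "d", "s", "Z", "m", "v", "se", "pe", "are", "p", "i",
)


def _principal_quantum_number(z: int) -> int:
    for n, top in enumerate((2, 10, 18, 36, 54, 86, 118), start=1):
        if z <= top:
            return n
    return 7


def _vdw_volume(z: int) -> float:
    r = _PT.GetRvdw(z)
    return 4.0 / 3.0 * math.pi * r ** 3


def atom_properties(mol: Chem.Mol) -> dict[str, np.ndarray]:
    """Vectors of all weighting properties over the heavy atoms of ``mol``.

    Returns a map property-code -> float array of length ``mol.GetNumAtoms()``
    (hydrogen-suppressed).  Unavailable element constants appear as NaN.
    """
    n = mol.GetNumAtoms()
    out = {code: np.full(n, np.nan) for code in PROPERTY_CODES}

    try:
        rdPartialCharges.ComputeGasteigerCharges(mol)
        charges_ok = True
    except Exception:
        charges_ok = False

    for idx, atom in enumerate(mol.GetAtoms()):
        z = atom.GetAtomicNum()
        degree = atom.GetDegree()  # heavy neighbours
        n_h = atom.GetTotalNumHs()
        zv = _PT.GetNOuterElecs(z)
        dv = zv - n_h  # Kier-Hall valence delta
        out["Z"][idx] = z
        out["m"][idx] = _PT.GetAtomicWeight(z)
        out["v"][idx] = _vdw_volume(z)
        out["d"][idx] = degree
        out["dv"][idx] = dv
        pqn = _principal_quantum_number(z)
        if degree > 0:
            out["s"][idx] = ((2.0 / pqn) ** 2 * dv + 1.0) / degree
        out["se"][idx] = SANDERSON_EN.get(z, np.nan)
        out["pe"][idx] = PAULING_EN.get(z, np.nan)
        out["are"][idx] = ALLRED_ROCHOW_EN.get(z, np.nan)
        out["p"][idx] = POLARIZABILITY.get(z, np.nan)
        out["i"][idx] = IONIZATION_EV.get(z, np.nan)
        if charges_ok:
            q = atom.GetDoubleProp("_GasteigerCharge")
            if atom.HasProp("_GasteigerHCharge"):
                q += atom.GetDoubleProp("_GasteigerHCharge")
            out["c"][idx] = q
    return out
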