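"""Topological autocorrelation descriptors on the hydrogen-suppressed graph.

Six families over twelve atomic weighting properties:

* ``ATS{k}{w}``   Moreau-Broto autocorrelation at topological lag k
* ``AATS{k}{w}``  averaged Moreau-Broto (per pair at lag k)
* ``ATSC{k}{w}``  centered Moreau-Broto (weights mean-centered)
* ``AATSC{k}{w}`` averaged centered
* ``MATS{k}{w}``  Moran coefficient
* ``GATS{k}{w}``  Geary coefficient

Lags run 0..8 for the Moreau-Broto variants and 1..8 for Moran/Geary
(both are undefined at lag 0), giving 4*9*12 + 2*8*12 = 624 descriptors.

Conventions: lag 0 is the sum of squared weights over atoms; for k >= 1 the
sum runs over unordered atom pairs at shortest-path distance k.  Any NaN in
the weight vector, or an empty lag (no pair at that distance), yields NaN.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdmolops

from .atomprops import PROPERTY_CODES, atom_properties

MAX_LAG = 8


def descriptor_names() -> list[str]:
    names: list[str] = []
    for fam, lag0 in (("ATS", 0), ("AATS", 0), ("ATSC", 0), ("AATSC", 0),
                      ("MATS", 1), ("GATS", 1)):
        for k in range(lag0, MAX_LAG + 1):
            for w in PROPERTY_CODES:
                names.append(f"{fam}{k}{w}")
    return names


def moreau_broto(weights: np.ndarray, dist: np.ndarray, lag: int) -> float:
    """Moreau-Broto autocorrelation of a weight vector at a topological lag.

    lag 0: sum of w_i^2; lag k>=1: sum over unordered pairs {i,j} with
    d(i,j) = k of w_i * w_j.
    """
    if np.isnan(weights).any():
        return float("nan")
    if lag == 0:
        return float(np.sum(weights ** 2))
    mask = np.triu(dist == lag, k=1)
    if not mask.any():
        return float("nan")
    return float(np.sum(np.outer(weights, weights)[mask]))


def _family_values(weights: np.ndarray, dist: np.ndarray) -> dict[str, list[float]]:
    n = len(weights)
    has_nan = np.isnan(weights).any()
    centered = weights - np.mean(weights) if not has_nan else weights
    out: dict[str, list[float]] = {f: [] for f in
                                   ("ATS", "AATS", "ATSC", "AATSC", "MATS", "GATS")}
    # pair counts per lag (lag 0 counts atoms)
    pair_count = [n] + [int(np.sum(np.triu(dist == k, k=1))) for k in
                        range(1, MAX_LAG + 1)]
    var = float(np.mean(centered ** 2)) if not has_nan else float("nan")
    denom_geary = (float(np.sum(centered ** 2)) / (n - 1)
                   if (not has_nan and n > 1) else float("nan"))

    for k in range(0, MAX_LAG + 1):
        ats = moreau_broto(weights, dist, k)
        atsc = moreau_broto(centered, dist, k)
        cnt = pair_count[k]
        out["ATS"].append(ats)
        out["AATS"].append(ats / cnt if cnt else float("nan"))
        out["ATSC"].append(atsc)
        out["AATSC"].append(atsc / cnt if cnt else float("nan"))
        if k >= 1:
            aatsc = atsc / cnt if cnt else float("nan")
            out["MATS"].append(aatsc / var if var else float("nan"))
            if cnt and not has_nan:
                mask = np.triu(dist == k, k=1)
                diff2 = (weights[:, None] - weights[None, :]) ** 2
                geary_num = float(np.sum(diff2[mask])) / (2.0 * cnt)
                out["GATS"].append(geary_num / denom_geary
                                   if denom_geary else float("nan"))
            else:
                out["GATS"].append(float("nan"))
    return out


def compute(mol: Chem.Mol) -> dict[str, float]:
    """All 624 autocorrelation descriptors for one molecule."""
    props = atom_properties(mol)
    dist = rdmolops.GetDistanceMatrix(mol)
    values: dict[str, float] = {}
    per_prop = {w: _family_values(props[w], dist) for w in PROPERTY_CODES}
    for fam, lag0 in (("ATS", 0), ("AATS", 0), ("ATSC", 0), ("AATSC", 0),
                      ("MATS", 1), ("GATS", 1)):
        for k in range(lag0, MAX_LAG + 1):
            for w in PROPERTY_CODES:
                values[f"{fam}{k}{w}"] = per_prop[w][fam][k - lag0]
    return values
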