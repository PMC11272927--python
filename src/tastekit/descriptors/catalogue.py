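"""The 1613-descriptor 2D catalogue.

The catalogue is assembled from nine families, all computable from molecular
topology alone (no 3D coordinates):

====================================  =====
family                                width
====================================  =====
topological autocorrelation            624
matrix spectral (A/L/D/Barysz)         132
rdkit physchem/topological/fragment    210
distance-matrix topological indices      8
atom-type E-state                      316
CATS2D pharmacophore pair counts       210
Galvez charge indices                   21
ring counts                             50
MQN (molecular quantum numbers)         42
====================================  =====

Failed computations (missing element constants, Gasteiger failures,
absent atom types) are recorded as NaN — missing, never zero.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors

from . import autocorr, estate, spectral, topo

logger = logging.getLogger(__name__)

#: catalogue width contract
CATALOGUE_SIZE = 1613

_RDKIT_DESCRIPTORS: list[tuple[str, object]] = list(Descriptors.descList)

MQN_NAMES = [f"MQN{i}" for i in range(1, 43)]


def catalogue_names() -> list[str]:
    """Ordered names of the full 2D descriptor catalogue."""
    names: list[str] = []
    names += autocorr.descriptor_names()
    names += spectral.descriptor_names()
    names += [name for name, _ in _RDKIT_DESCRIPTORS]
    names += estate.descriptor_names()
    names += topo.cats2d_names()
    names += topo.galvez_names()
    names += list(topo.TOPOINDEX_NAMES)
    names += topo.ring_names()
    names += MQN_NAMES
    return names


_NAMES = catalogue_names()
if len(_NAMES) != CATALOGUE_SIZE:  # pragma: no cover - engine drift guard
    logger.warning(
        "descriptor catalogue width %d differs from the expected %d "
        "(descriptor-engine drift); proceeding with the available columns",
        len(_NAMES), CATALOGUE_SIZE)
if len(set(_NAMES)) != len(_NAMES):  # pragma: no cover
    raise RuntimeError("duplicate descriptor names in catalogue")


def _safe(fn, mol) -> float:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            value = fn(mol)
    except Exception:
        return float("nan")
    if value is None:
        return float("nan")
    value = float(value)
    return value if np.isfinite(value) else float("nan")


def compute_row(mol: Chem.Mol) -> dict[str, float]:
    """All catalogue descriptors for one (standardized, valid) molecule."""
    values: dict[str, float] = {}
    values.update(autocorr.compute(mol))
    values.update(spectral.compute(mol))
    for name, fn in _RDKIT_DESCRIPTORS:
        values[name] = _safe(fn, mol)
    values.update(estate.compute(mol))
    values.update(topo.cats2d(mol))
    values.update(topo.galvez(mol))
    values.update(topo.topoindex(mol))
    values.update(topo.ring_counts(mol))
    try:
        mqn = rdMolDescriptors.MQNs_(mol)
        values.update({n: float(v) for n, v in zip(MQN_NAMES, mqn)})
    except Exception:
        values.update({n: float("nan") for n in MQN_NAMES})
    return values
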