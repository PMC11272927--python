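"""Atom-type electrotopological-state descriptors.

For each of the 79 Kier-Hall E-state atom types: the count of matching atoms
(``N<type>``), the sum of their E-state indices (``S<type>``), and the max /
min index (``MAX<type>`` / ``MIN<type>``; NaN when the type is absent, which
is the dominant source of structural missingness in the descriptor table) —
316 descriptors.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem.EState import AtomTypes
from rdkit.Chem.EState.EState import EStateIndices

AtomTypes.BuildPatts()
ESTATE_TYPES: tuple[str, ...] = tuple(name for name, _ in AtomTypes.esPatterns)


def descriptor_names() -> list[str]:
    names: list[str] = []
    for prefix in ("N", "S", "MAX", "MIN"):
        names.extend(f"{prefix}{t}" for t in ESTATE_TYPES)
    return names


def compute(mol: Chem.Mol) -> dict[str, float]:
    types = AtomTypes.TypeAtoms(mol)
    indices = EStateIndices(mol) if mol.GetNumAtoms() else np.zeros(0)
    per_type: dict[str, list[float]] = {t: [] for t in ESTATE_TYPES}
    for atom_types, value in zip(types, indices):
        for t in atom_types:
            if t in per_type:
                per_type[t].append(float(value))

    values: dict[str, float] = {}
    for t in ESTATE_TYPES:
        vals = per_type[t]
        values[f"N{t}"] = float(len(vals))
        values[f"S{t}"] = float(sum(vals))
        values[f"MAX{t}"] = max(vals) if vals else float("nan")
        values[f"MIN{t}"] = min(vals) if vals else float("nan")
    return values
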