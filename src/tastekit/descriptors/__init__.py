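"""Descriptor table computation and pre-processing.

Pipeline: :func:`compute_descriptors` (raw) → :func:`drop_sparse_features`
(filtered, missing fraction > 30% discarded) → :func:`knn_impute` (imputed,
k = 20) → :func:`fit_normalization` / :func:`apply_normalization`
(normalized, per-feature min-max to [0, 1], fitted on train only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.impute import KNNImputer

from ..chemio import MoleculeRecord
from .catalogue import CATALOGUE_SIZE, catalogue_names, compute_row

__all__ = [
    "CATALOGUE_SIZE", "DescriptorTable", "NormalizationParams",
    "catalogue_names", "compute_descriptors", "drop_sparse_features",
    "knn_impute", "fit_normalization", "apply_normalization",
]

logger = logging.getLogger(__name__)

STATES = ("raw", "filtered", "imputed", "normalized")


@dataclass
class DescriptorTable:
    """Compounds × named numeric features; NaN marks a missing value."""

    data: pd.DataFrame
    state: str = "raw"
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        if self.state == "normalized":
            values = self.data.to_numpy(dtype=float)
            if np.isnan(values).any():
                raise ValueError("normalized table contains missing values")
            if values.size and (values.min() < -1e-12 or values.max() > 1 + 1e-12):
                raise ValueError("normalized table has values outside [0, 1]")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path)  # NaN serialized as empty field

    @classmethod
    def from_csv(cls, path: str | Path, state: str = "raw") -> "DescriptorTable":
        return cls(pd.read_csv(path, index_col=0), state=state)


@dataclass
class NormalizationParams:
    """Frozen per-feature min/max from the fitting (training) table."""

    minimum: pd.Series
    maximum: pd.Series
    fitted_on: str = ""

    def __post_init__(self) -> None:
        if (self.maximum < self.minimum).any():
            raise ValueError("per-feature max below min")


def compute_descriptors(records: Sequence[MoleculeRecord]) -> DescriptorTable:
    """One catalogue row per curated record (state: raw).

    Records must be standardized; an unparseable canonical SMILES raises,
    since fatal records are expected to have been removed during curation.
    """
    names = catalogue_names()
    rows, ids = [], []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.canonical_smiles)
        if mol is None:
            raise ValueError(
                f"record {rec.id!r} has no valid canonical SMILES; "
                "run standardize/deduplicate first")
        values = compute_row(mol)
        rows.append([values[n] for n in names])
        ids.append(rec.id)
    data = pd.DataFrame(rows, index=ids, columns=names, dtype=float)
    return DescriptorTable(data, state="raw")


def drop_sparse_features(table: DescriptorTable,
                         max_missing_fraction: float = 0.30) -> DescriptorTable:
    """Discard features whose missing fraction strictly exceeds the threshold."""
    if table.state != "raw":
        raise ValueError(f"expected a raw table, got state {table.state!r}")
    frac = table.data.isna().mean(axis=0)
    dropped = list(frac.index[frac > max_missing_fraction])
    kept = table.data.drop(columns=dropped)
    if kept.shape[1] == 0:
        raise ValueError("all features exceeded the missing-value threshold")
    logger.info("dropped %d/%d sparse features (>%g%% missing)",
                len(dropped), table.data.shape[1], 100 * max_missing_fraction)
    return DescriptorTable(kept, state="filtered",
                           log={**table.log, "dropped_features": dropped})


def knn_impute(table: DescriptorTable, k: int = 20) -> DescriptorTable:
    """Replace each missing cell by the mean of that feature over the k
    nearest rows (NaN-aware Euclidean distance on mutually observed
    features); k is capped at the number of eligible rows."""
    if table.state != "filtered":
        raise ValueError(f"expected a filtered table, got state {table.state!r}")
    values = table.values
    if np.isnan(values).all(axis=1).any():
        bad = [table.compound_ids[i]
               for i in np.flatnonzero(np.isnan(values).all(axis=1))]
        raise ValueError(f"rows with all features missing: {bad}")
    n_eligible = max(1, values.shape[0] - 1)
    imputer = KNNImputer(n_neighbors=min(k, n_eligible))
    filled = imputer.fit_transform(values)
    # KNNImputer drops all-NaN columns; restore them as zero-filled and flag
    if filled.shape[1] != values.shape[1]:
        all_nan = np.isnan(values).all(axis=0)
        restored = np.zeros_like(values)
        restored[:, ~all_nan] = filled
        filled = restored
        logger.info("zero-filled %d all-missing features", int(all_nan.sum()))
    data = pd.DataFrame(filled, index=table.compound_ids,
                        columns=table.feature_names)
    return DescriptorTable(data, state="imputed", log=dict(table.log))


def fit_normalization(table: DescriptorTable,
                      fitted_on: str = "train") -> NormalizationParams:
    if table.state != "imputed":
        raise ValueError(f"expected an imputed table, got state {table.state!r}")
    return NormalizationParams(minimum=table.data.min(axis=0),
                               maximum=table.data.max(axis=0),
                               fitted_on=fitted_on)


def apply_normalization(table: DescriptorTable,
                        params: NormalizationParams) -> DescriptorTable:
    """Min-max scale to [0, 1] with frozen params; constant features map to 0,
    out-of-range values (unseen at fit time) are clipped."""
    unknown = set(table.feature_names) - set(params.minimum.index)
    if unknown:
        raise ValueError(f"features absent from normalization params: "
                         f"{sorted(unknown)[:5]}...")
    lo = params.minimum[table.feature_names]
    hi = params.maximum[table.feature_names]
    span = hi - lo
    constant = span == 0
    scaled = ((table.data - lo) / span.replace(0.0, np.nan)).clip(0.0, 1.0)
    scaled.loc[:, constant[constant].index] = 0.0
    return DescriptorTable(scaled, state="normalized", log=dict(table.log))
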