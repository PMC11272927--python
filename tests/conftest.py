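"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tastekit import chemio
from tastekit.descriptors import (DescriptorTable, apply_normalization,
                                  drop_sparse_features, fit_normalization,
                                  knn_impute)
from tastekit.synthetic import fixture_molecules, generate_dataset

BALANCED_CLASSES = ("bitter", "sweet", "other", "umami")


@pytest.fixture(scope="session")
def curated_fixtures():
    """Fixture molecules after standardization and deduplication."""
    std = [chemio.standardize(r) for r in fixture_molecules()]
    return chemio.deduplicate(std)


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-signal dataset shared by model-level tests."""
    return generate_dataset(
        n_per_class={c: 40 for c in BALANCED_CLASSES},
        n_features=30, n_informative=8, shift=2.5,
        missing_rate=0.02, seed=7)


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    table = knn_impute(drop_sparse_features(small_dataset.table), k=10)
    return apply_normalization(table, fit_normalization(table))


def make_table(values, state="normalized", columns=None):
    values = np.asarray(values, dtype=float)
    columns = columns or [f"f{j}" for j in range(values.shape[1])]
    return DescriptorTable(
        pd.DataFrame(values, columns=columns,
                     index=[f"r{i}" for i in range(values.shape[0])]),
        state=state)
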