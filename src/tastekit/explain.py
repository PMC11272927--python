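"""Shapley attributions per taste class, global ranking, and correlations.

For the (tree-ensemble) final model, exact path-dependent Tree-Shapley
values are computed per class probability; for a non-tree model the module
falls back to seeded permutation-sampling Shapley estimates (flagged in the
returned report).  The global importance of a feature is the mean over
classes of the mean absolute attribution, which is how the selected features
are ranked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from ._treeshap import forest_shap
from .modelkit import TastePredictor, predict_proba

logger = logging.getLogger(__name__)


@dataclass
class Attribution:
    values: np.ndarray            # (n_samples, n_features)
    base_value: float
    feature_names: list[str]
    class_name: str
    method: str                   # "tree" or "permutation"


def _permutation_shap(model, X: np.ndarray, background: np.ndarray,
                      class_index: int, class_order, n_permutations: int,
                      seed: int) -> tuple[np.ndarray, float]:
    """Sampling Shapley estimate: marginal contributions over random feature
    orderings, with out-of-coalition features replaced by background rows."""
    rng = np.random.default_rng(seed)
    n, m = X.shape
    phi = np.zeros((n, m))
    base = float(predict_proba(model, background, class_order)
                 [:, class_index].mean())
    for s in range(n):
        for _ in range(n_permutations):
            order = rng.permutation(m)
            bg = background[rng.integers(len(background))]
            current = bg.copy()
            prev = float(predict_proba(model, current[None, :], class_order)
                         [0, class_index])
            for f in order:
                current[f] = X[s, f]
                new = float(predict_proba(model, current[None, :],
                                          class_order)[0, class_index])
                phi[s, f] += new - prev
                prev = new
    return phi / n_permutations, base


def shapley_values(predictor: TastePredictor, X: np.ndarray,
                   class_index: int, n_permutations: int = 20,
                   seed: int = 0) -> Attribution:
    """Per-sample, per-feature attributions of one class probability.

    ``X`` must be the normalized matrix restricted to the predictor's
    selected features.  Local accuracy holds for the tree route:
    base_value + row sum = predicted class probability.
    """
    X = np.asarray(X, dtype=float)
    class_name = predictor.class_order[class_index]
    model = predictor.model
    if isinstance(model, RandomForestClassifier):
        model_col = list(model.classes_).index(class_name)
        values, base = forest_shap(model, X, model_col)
        method = "tree"
    else:
        logger.warning("non-tree model: falling back to permutation-sampling "
                       "Shapley (seed=%d)", seed)
        values, base = _permutation_shap(
            model, X, X, class_index, predictor.class_order,
            n_permutations, seed)
        method = "permutation"
    return Attribution(values=values, base_value=base,
                       feature_names=list(predictor.selected_features),
                       class_name=class_name, method=method)


def rank_features(attributions: dict[str, Attribution]) -> pd.DataFrame:
    """Global ranking: importance(f) = mean over classes of mean |phi_f|.

    Returns a DataFrame (feature, importance, rank) sorted by descending
    importance, ties broken alphabetically.
    """
    names = None
    per_class = []
    for cls, attr in attributions.items():
        if names is None:
            names = attr.feature_names
        elif names != attr.feature_names:
            raise ValueError("mismatched feature sets across classes")
        per_class.append(np.abs(attr.values).mean(axis=0))
    importance = np.mean(per_class, axis=0)
    frame = pd.DataFrame({"feature": names, "importance": importance})
    frame = frame.sort_values(["importance", "feature"],
                              ascending=[False, True], kind="stable")
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame.reset_index(drop=True)


def feature_correlation(data: pd.DataFrame,
                        feature_subset: list[str] | None = None
                        ) -> pd.DataFrame:
    """Pearson correlation matrix of the selected features.

    Diagonal is exactly 1; zero-variance features yield NaN off-diagonal
    entries (undefined correlation) and are logged.
    """
    if feature_subset is not None:
        missing = set(feature_subset) - set(data.columns)
        if missing:
            raise ValueError(f"features not in table: {sorted(missing)}")
        data = data[feature_subset]
    if len(data) < 2:
        raise ValueError("correlation needs at least 2 samples")
    constant = data.columns[data.std(ddof=0) == 0]
    if len(constant):
        logger.warning("zero-variance features with undefined correlations: %s",
                       list(constant))
    corr = data.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    corr.loc[constant, :] = np.nan
    corr.loc[:, constant] = np.nan
    for c in constant:
        corr.loc[c, c] = 1.0
    return corr
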