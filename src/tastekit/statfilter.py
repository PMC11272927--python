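"""Statistical screening of descriptors across the four taste classes.

Features are screened with the Kruskal-Wallis rank test (the Shapiro-Wilk
test is computed as a diagnostic only: descriptor distributions are typically
non-normal, which is what justifies the non-parametric route), p-values are
converted to q-values with the Benjamini-Hochberg FDR step-up, and features
with q below the threshold (default 0.05) are selected.  One-vs-rest
Mann-Whitney tests rank the features that most differentiate each single
taste from the pooled rest, and a centered PCA provides the low-dimensional
projection used to visualize class structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .descriptors import DescriptorTable

logger = logging.getLogger(__name__)


@dataclass
class FeatureScreenResult:
    feature_name: str
    normality_p: float
    kw_H: float
    kw_p: float
    q_value: float
    selected: bool
    flags: tuple[str, ...] = ()


def normality_test(values: np.ndarray) -> float:
    """Shapiro-Wilk p-value; NaN (undefined, treated as non-normal) for
    constant samples, error below n = 3."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(values) == 0:
        return float("nan")
    return float(stats.shapiro(values).pvalue)


def kruskal_wallis(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    labels = np.asarray(labels)
    groups = [np.asarray(values)[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two classes")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty class")
    if np.ptp(np.asarray(values, dtype=float)) == 0:
        return 0.0, 1.0  # identical ranks everywhere
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_features(table: DescriptorTable, labels,
                    q_threshold: float = 0.05) -> list[FeatureScreenResult]:
    """Per-feature Kruskal-Wallis + BH; ``selected`` ⇔ q < threshold.

    Zero-variance features are never selected and carry a ``zero-variance``
    flag (their test is undefined).
    """
    labels = np.asarray(labels)
    X = table.values
    names = table.feature_names
    kw_h = np.full(len(names), np.nan)
    kw_p = np.ones(len(names))
    norm_p = np.full(len(names), np.nan)
    flags: list[tuple[str, ...]] = []
    for j, name in enumerate(names):
        col = X[:, j]
        if np.ptp(col) == 0:
            flags.append(("zero-variance",))
            kw_h[j], kw_p[j] = 0.0, 1.0
            continue
        flags.append(())
        norm_p[j] = normality_test(col) if col.size >= 3 else float("nan")
        kw_h[j], kw_p[j] = kruskal_wallis(col, labels)
    q = bh_adjust(kw_p)
    results = [
        FeatureScreenResult(
            feature_name=name, normality_p=float(norm_p[j]),
            kw_H=float(kw_h[j]), kw_p=float(kw_p[j]), q_value=float(q[j]),
            selected=bool(q[j] < q_threshold) and "zero-variance" not in flags[j],
            flags=flags[j])
        for j, name in enumerate(names)
    ]
    n_sel = sum(r.selected for r in results)
    logger.info("screened %d features: %d selected at q < %g",
                len(results), n_sel, q_threshold)
    return results


def screen_to_frame(results: list[FeatureScreenResult]) -> pd.DataFrame:
    """Screen report as a DataFrame (columns feature,H,p,q,selected)."""
    return pd.DataFrame({
        "feature": [r.feature_name for r in results],
        "H": [r.kw_H for r in results],
        "p": [r.kw_p for r in results],
        "q": [r.q_value for r in results],
        "selected": [r.selected for r in results],
    })


def mann_whitney_ovr(table: DescriptorTable, labels,
                     top_k: int = 5) -> dict[str, pd.DataFrame]:
    """For each class: Mann-Whitney U of every feature, class vs pooled rest.

    Returns per class a DataFrame (feature, U, p) of the ``top_k`` features
    with smallest p (all features if top_k exceeds the feature count).
    P-values are reported unadjusted: this ranking feeds the heatmap-style
    report, not feature selection.
    """
    labels = np.asarray(labels)
    X = table.values
    names = np.asarray(table.feature_names)
    out: dict[str, pd.DataFrame] = {}
    for cls in np.unique(labels):
        mask = labels == cls
        if mask.sum() == 0 or (~mask).sum() == 0:
            raise ValueError(f"class {cls!r} or its complement is empty")
        u = np.empty(len(names))
        p = np.empty(len(names))
        for j in range(len(names)):
            if np.ptp(X[:, j]) == 0:
                u[j], p[j] = mask.sum() * (~mask).sum() / 2.0, 1.0
                continue
            res = stats.mannwhitneyu(X[mask, j], X[~mask, j],
                                     alternative="two-sided")
            u[j], p[j] = float(res.statistic), float(res.pvalue)
        order = np.argsort(p, kind="stable")[:min(top_k, len(names))]
        out[str(cls)] = pd.DataFrame(
            {"feature": names[order], "U": u[order], "p": p[order]}
        ).reset_index(drop=True)
    return out


def pca_project(table: DescriptorTable,
                n_components: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA scores and explained-variance fractions."""
    X = table.values
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows, features)="
            f"{min(X.shape)}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_
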