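"""Exact path-dependent Shapley attribution for sklearn decision trees.

Implements the polynomial-time Tree-SHAP recursion: a path of (feature,
zero-fraction, one-fraction, weight) elements is extended at every split and
unwound when a feature repeats, so each leaf contributes its exact weighted
Shapley terms.  The conditional expectation behind the game is the
cover-weighted ("path-dependent") one: when a feature is out of the
coalition, both children are taken in proportion to their training cover.

Local accuracy: base_value + sum(phi) equals the tree output for every
sample, which the test suite asserts together with agreement to a
brute-force subset-enumeration oracle on small trees.
"""

from __future__ import annotations

import numpy as np

__all__ = ["tree_shap", "tree_expected_value", "forest_shap"]


def _extend(m: list[list[float]], pz: float, po: float, pi: int) -> list[list[float]]:
    m = [e.copy() for e in m]
    m.append([pi, pz, po, 1.0 if not m else 0.0])
    l = len(m)
    for i in range(l - 2, -1, -1):
        m[i + 1][3] += po * m[i][3] * (i + 1) / l
        m[i][3] = pz * m[i][3] * (l - 1 - i) / l
    return m


def _unwind(m: list[list[float]], i: int) -> list[list[float]]:
    m = [e.copy() for e in m]
    l = len(m)
    n = m[l - 1][3]
    o_i, z_i = m[i][2], m[i][1]
    for j in range(l - 2, -1, -1):
        if o_i != 0:
            t = m[j][3]
            m[j][3] = n * l / ((j + 1) * o_i)
            n = t - m[j][3] * z_i * (l - 1 - j) / l
        else:
            m[j][3] = m[j][3] * l / (z_i * (l - 1 - j))
    for j in range(i, l - 1):
        m[j][0], m[j][1], m[j][2] = m[j + 1][0], m[j + 1][1], m[j + 1][2]
    m.pop()
    return m


def tree_shap(children_left: np.ndarray, children_right: np.ndarray,
              feature: np.ndarray, threshold: np.ndarray,
              values: np.ndarray, cover: np.ndarray,
              x: np.ndarray, n_features: int) -> np.ndarray:
    """Shapley attributions of one tree's scalar output for one sample."""
    phi = np.zeros(n_features)

    def recurse(node: int, m: list[list[float]], pz: float, po: float,
                pi: int) -> None:
        m = _extend(m, pz, po, pi)
        if children_left[node] < 0:  # leaf
            for i in range(1, len(m)):
                w = sum(e[3] for e in _unwind(m, i))
                d, z, o = int(m[i][0]), m[i][1], m[i][2]
                phi[d] += w * (o - z) * values[node]
            return
        f = int(feature[node])
        hot, cold = ((children_left[node], children_right[node])
                     if x[f] <= threshold[node]
                     else (children_right[node], children_left[node]))
        iz = io = 1.0
        k = next((idx for idx in range(1, len(m)) if m[idx][0] == f), None)
        if k is not None:
            iz, io = m[k][1], m[k][2]
            m = _unwind(m, k)
        recurse(hot, m, iz * cover[hot] / cover[node], io, f)
        recurse(cold, m, iz * cover[cold] / cover[node], 0.0, f)

    recurse(0, [], 1.0, 1.0, -1)
    return phi


def tree_expected_value(children_left: np.ndarray, values: np.ndarray,
                        cover: np.ndarray) -> float:
    """Cover-weighted mean leaf output (the tree's base value)."""
    leaves = children_left < 0
    return float(np.sum(values[leaves] * cover[leaves]) / cover[0])


def _tree_arrays(estimator, class_index: int):
    t = estimator.tree_
    value = t.value.reshape(t.node_count, -1)
    if value.shape[1] > 1:  # classification: per-node class probabilities
        out = value[:, class_index] / value.sum(axis=1)
    else:
        out = value[:, 0]
    return (t.children_left, t.children_right, t.feature, t.threshold,
            out, t.weighted_n_node_samples)


def forest_shap(forest, X: np.ndarray, class_index: int
                ) -> tuple[np.ndarray, float]:
    """Attributions of a random forest's class probability.

    Returns ``(phi, base_value)`` with ``phi`` of shape (n_samples,
    n_features); the forest output is the mean of per-tree leaf class
    frequencies, so attributions and base values average over trees.
    """
    X = np.asarray(X, dtype=float)
    n_samples, n_features = X.shape
    phi = np.zeros((n_samples, n_features))
    base = 0.0
    for estimator in forest.estimators_:
        arrays = _tree_arrays(estimator, class_index)
        base += tree_expected_value(arrays[0], arrays[4], arrays[5])
        for s in range(n_samples):
            phi[s] += tree_shap(*arrays, X[s], n_features)
    n_trees = len(forest.estimators_)
    return phi / n_trees, base / n_trees
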