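"""Applicability-domain scoring by fingerprint similarity to the training set.

A query compound's applicability score is the mean Tanimoto similarity of
its Morgan fingerprint (1024 bits, radius 2) to its 5 nearest training
compounds.  Model reliability across the chemical space is assessed by
splitting the scored test set into 10 equal-frequency similarity bins and
evaluating the classification metrics in each bin: a model with a broad
applicability domain shows per-bin accuracy statistically indistinguishable
from the global accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chemio import TASTE_CLASSES
from .modelkit import compute_metrics

logger = logging.getLogger(__name__)

_GENERATOR_CACHE: dict[tuple[int, int], object] = {}


def morgan_fingerprint(smiles: str, n_bits: int = 1024,
                       radius: int = 2) -> np.ndarray:
    """Hashed circular-substructure bit vector as a 0/1 uint8 array."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    key = (n_bits, radius)
    if key not in _GENERATOR_CACHE:
        _GENERATOR_CACHE[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits)
    fp = _GENERATOR_CACHE[key].GetFingerprintAsNumPy(mol)
    return fp.astype(np.uint8)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a ∧ b| / |a ∨ b|; 0 by convention when both vectors are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def avg_topk_similarity(query_fp: np.ndarray, train_fps: np.ndarray,
                        k: int = 5, exclude_self: bool = True) -> float:
    """Mean of the k largest Tanimoto similarities to the training set.

    With fewer than k training compounds, all are averaged.  When
    ``exclude_self`` is set, one exact-identity match (similarity within
    1e-12 of 1 for an identical fingerprint) is removed so that scoring a
    training compound against its own set is not trivially 1.
    """
    train_fps = np.asarray(train_fps)
    if train_fps.ndim != 2 or len(train_fps) == 0:
        raise ValueError("empty training fingerprint set")
    sims = np.array([tanimoto(query_fp, fp) for fp in train_fps])
    if exclude_self:
        identical = np.flatnonzero(
            (train_fps == np.asarray(query_fp, dtype=train_fps.dtype))
            .all(axis=1))
        if len(identical):
            sims = np.delete(sims, identical[0])
        if len(sims) == 0:
            raise ValueError("training set contains only the query itself")
    top = np.sort(sims)[::-1][:k]
    return float(top.mean())


@dataclass
class SimilarityReport:
    scores: pd.DataFrame          # id, avg_top5, bin
    per_bin: pd.DataFrame         # bin, n, acc, f1, ... per similarity bin
    merged_bins: bool             # True when duplicate quantile edges collapsed


def performance_by_similarity(predictions, truths, scores,
                              n_bins: int = 10,
                              class_order=TASTE_CLASSES,
                              probs: np.ndarray | None = None,
                              ids=None) -> SimilarityReport:
    """Equal-frequency similarity binning with per-bin metrics.

    Duplicate quantile edges (many identical scores) are merged, reducing
    the bin count; this is flagged in the report.
    """
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    scores = np.asarray(scores, dtype=float)
    if not (len(predictions) == len(truths) == len(scores)):
        raise ValueError("predictions, truths and scores must align")
    if len(scores) < n_bins:
        raise ValueError(f"{len(scores)} samples cannot fill {n_bins} bins")

    binned, edges = pd.qcut(scores, q=n_bins, labels=False,
                            retbins=True, duplicates="drop")
    n_effective = max(len(edges) - 1, 1)
    if len(edges) < 2:  # all scores identical: one degenerate bin
        binned = np.zeros(len(scores), dtype=int)
        edges = np.array([scores[0], scores[0]])
    merged = n_effective < n_bins
    if merged:
        logger.warning("duplicate quantile edges: %d bins merged into %d",
                       n_bins, n_effective)

    rows = []
    for b in range(n_effective):
        in_bin = binned == b
        if probs is not None:
            p = probs[in_bin]
        else:  # metrics that need probabilities get one-hot of predictions
            p = np.zeros((int(in_bin.sum()), len(class_order)))
            for i, pred in enumerate(predictions[in_bin]):
                p[i, list(class_order).index(pred)] = 1.0
        mv = compute_metrics(truths[in_bin], predictions[in_bin], p,
                             class_order)
        rows.append({"bin": b,
                     "score_lo": float(edges[b]),
                     "score_hi": float(edges[b + 1]),
                     "n": int(in_bin.sum()), "acc": mv.acc, "f1": mv.f1,
                     "f2": mv.f2, "precision": mv.precision,
                     "recall": mv.recall, "auc": mv.auc})
    per_bin = pd.DataFrame(rows)
    score_table = pd.DataFrame({
        "id": ids if ids is not None else np.arange(len(scores)),
        "avg_top5": scores, "bin": binned})
    return SimilarityReport(scores=score_table, per_bin=per_bin,
                            merged_bins=merged)


def score_compounds(query_smiles, train_smiles, k: int = 5,
                    n_bits: int = 1024, radius: int = 2) -> np.ndarray:
    """avg_top5 applicability score for each query against the training set."""
    train_fps = np.array([morgan_fingerprint(s, n_bits, radius)
                          for s in train_smiles])
    return np.array([
        avg_topk_similarity(morgan_fingerprint(s, n_bits, radius),
                            train_fps, k=k)
        for s in query_smiles])
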