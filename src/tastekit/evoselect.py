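"""Multi-objective Pareto-based evolutionary model construction.

A genetic algorithm jointly searches (a) the descriptor subset, (b) the
classifier family (random forest vs SVM) and (c) its hyperparameters.  Each
candidate is scored by stratified cross-validation on nine objectives, all
oriented as maximizations in [0, 1]:

    feature-count minimization, ACC, F1, F2, precision, recall, AUC,
    model-complexity minimization, and a probability-distance term
    (1 − mean Manhattan distance between out-of-fold class-probability
    vectors and the one-hot truth, halved into [0, 1]).

Candidates are compared both by Pareto dominance (the returned front) and by
a weighted scalar fitness (default weights 1/10/10/1/1/10/1/1/1, maximum 36)
used for tournament selection and final-model choice.

Genome: feature bit-mask ++ family bit ++ three real-coded hyperparameter
genes (tree-count fraction, log10 C, log10 gamma).  Two-point crossover acts
on the concatenated genome; mutation is per-gene bit-flip / Gaussian.  The
current Pareto front survives unchanged (elitism), so the best scalar
fitness is non-decreasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .modelkit import ClassifierSpec, CVResult, MetricVector, cross_validate

logger = logging.getLogger(__name__)

N_OBJECTIVES = 9
OBJECTIVE_NAMES = ("feat_min", "acc", "f1", "f2", "precision", "recall",
                   "auc", "complexity_min", "manhattan")


@dataclass(frozen=True)
class FitnessWeights:
    """Objective weights of the scalar fitness (defaults sum to 36)."""

    w_feat_min: float = 1.0
    w_acc: float = 10.0
    w_f1: float = 10.0
    w_f2: float = 1.0
    w_prc: float = 1.0
    w_rec: float = 10.0
    w_auc: float = 1.0
    w_complexity_min: float = 1.0
    w_manhattan: float = 1.0

    def as_array(self) -> np.ndarray:
        arr = np.array([self.w_feat_min, self.w_acc, self.w_f1, self.w_f2,
                        self.w_prc, self.w_rec, self.w_auc,
                        self.w_complexity_min, self.w_manhattan])
        if (arr < 0).any():
            raise ValueError("weights must be non-negative")
        return arr


@dataclass
class EvoConfig:
    population_size: int = 100
    max_generations: int = 200
    p_arithmetic_crossover: float = 0.0
    p_mutation: float = 0.01
    p_two_point_crossover: float = 0.9
    n_runs: int = 10
    cv_folds: int = 10
    tournament_size: int = 2
    weights: FitnessWeights = field(default_factory=FitnessWeights)
    seed: int = 0
    rf_trees_range: tuple[int, int] = (10, 200)
    svm_log_c_range: tuple[float, float] = (-3.0, 3.0)
    svm_log_gamma_range: tuple[float, float] = (-3.0, 3.0)
    init_mask_density: float = 0.5
    families: tuple[str, ...] = ("random_forest", "svm")

    def __post_init__(self) -> None:
        for p in (self.p_arithmetic_crossover, self.p_mutation,
                  self.p_two_point_crossover):
            if not 0.0 <= p <= 1.0:
                raise ValueError("operator probabilities must lie in [0, 1]")
        if self.population_size < 1 or self.max_generations < 1:
            raise ValueError("population size and generations must be positive")


@dataclass(eq=False)
class Individual:
    """One candidate: feature mask, family bit and real-coded hyperparams."""

    mask: np.ndarray                 # bool vector over candidate features
    family: str
    genes: np.ndarray                # (trees_frac, log10 C, log10 gamma)
    objectives: np.ndarray | None = None
    metrics: MetricVector | None = None
    fitness: float | None = None

    def genome_key(self) -> tuple:
        return (self.mask.tobytes(), self.family,
                tuple(np.round(self.genes, 12)))

    def spec(self, config: EvoConfig, seed: int = 0) -> ClassifierSpec:
        lo, hi = config.rf_trees_range
        if self.family == "random_forest":
            n_trees = int(round(lo + self.genes[0] * (hi - lo)))
            return ClassifierSpec("random_forest",
                                  {"n_trees": max(1, n_trees)}, seed=seed)
        c_lo, c_hi = config.svm_log_c_range
        g_lo, g_hi = config.svm_log_gamma_range
        return ClassifierSpec("svm", {
            "C": 10.0 ** float(np.clip(self.genes[1], c_lo, c_hi)),
            "gamma": 10.0 ** float(np.clip(self.genes[2], g_lo, g_hi)),
            "kernel": "rbf"}, seed=seed)

    @property
    def n_features(self) -> int:
        return int(self.mask.sum())


def _random_individual(n_features: int, config: EvoConfig,
                       rng: np.random.Generator) -> Individual:
    mask = rng.random(n_features) < config.init_mask_density
    ind = Individual(mask=mask,
                     family=str(rng.choice(config.families)),
                     genes=rng.random(3) * np.array([1.0, 6.0, 6.0])
                     + np.array([0.0, -3.0, -3.0]))
    _repair(ind, rng)
    return ind


def _repair(ind: Individual, rng: np.random.Generator) -> None:
    if not ind.mask.any():
        ind.mask[rng.integers(len(ind.mask))] = True
        logger.debug("repaired empty feature mask")


def manhattan_score(probs: np.ndarray, y: np.ndarray,
                    class_order: Sequence[str]) -> float:
    """1 − (mean L1 distance between probability rows and one-hot truth)/2.

    The L1 distance between a probability vector and a one-hot vector lies
    in [0, 2], so the score is a proper [0, 1] maximization objective.
    """
    onehot = np.zeros_like(probs)
    order = list(class_order)
    for i, label in enumerate(np.asarray(y)):
        onehot[i, order.index(label)] = 1.0
    return float(1.0 - np.abs(probs - onehot).sum(axis=1).mean() / 2.0)


def evaluate(ind: Individual, X: np.ndarray, y: np.ndarray,
             config: EvoConfig, k: int | None = None) -> np.ndarray:
    """Nine-objective evaluation via stratified CV on the masked features.

    Minimization objectives are rescaled to maximizations:
    ``1 − n_selected/m`` and ``1 − complexity/maximum`` (maximum = largest
    tree count for forests, training-set size for SVM support vectors).
    Deterministic given ``config.seed``; the result is cached on the
    individual.
    """
    rng = np.random.default_rng(config.seed)
    _repair(ind, rng)
    k = k or config.cv_folds
    X = np.asarray(X, dtype=float)
    cols = np.flatnonzero(ind.mask)
    spec = ind.spec(config, seed=config.seed)
    cv: CVResult = cross_validate(spec, X[:, cols], np.asarray(y),
                                  k=k, seed=config.seed)
    m = ind.mask.size
    feat_score = 1.0 - len(cols) / m
    if ind.family == "random_forest":
        max_complexity = config.rf_trees_range[1]
    else:
        max_complexity = len(np.asarray(y))
    complexity_score = max(0.0, 1.0 - cv.mean.complexity / max_complexity)
    auc = 0.0 if np.isnan(cv.mean.auc) else cv.mean.auc
    dist = manhattan_score(cv.oof_probs, y, cv.class_order)
    objectives = np.array([
        feat_score, cv.mean.acc, cv.mean.f1, cv.mean.f2, cv.mean.precision,
        cv.mean.recall, auc, complexity_score, dist])
    metrics = cv.mean
    metrics.n_features = len(cols)
    metrics.distance_term = dist
    ind.objectives = objectives
    ind.metrics = metrics
    ind.fitness = scalar_fitness(objectives, config.weights)
    return objectives


def scalar_fitness(objectives: np.ndarray,
                   weights: FitnessWeights | np.ndarray) -> float:
    """Weighted sum of the nine objectives (all in [0, 1])."""
    w = weights.as_array() if isinstance(weights, FitnessWeights) else \
        np.asarray(weights, dtype=float)
    obj = np.asarray(objectives, dtype=float)
    if obj.shape != w.shape:
        raise ValueError("objective/weight length mismatch")
    return float(obj @ w)


def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(a >= b) and np.any(a > b))


def pareto_front(population: Sequence[Individual]) -> list[Individual]:
    """Non-dominated individuals; duplicated objective vectors are all kept
    (non-strict dominance cannot remove an equal vector)."""
    front = []
    for ind in population:
        if ind.objectives is None:
            raise ValueError("all individuals must be evaluated")
        if not any(dominates(other.objectives, ind.objectives)
                   for other in population if other is not ind):
            front.append(ind)
    return front


# -- variation operators -----------------------------------------------------

def _genome_to_vector(ind: Individual) -> np.ndarray:
    fam_bit = 1.0 if ind.family == "svm" else 0.0
    return np.concatenate([ind.mask.astype(float), [fam_bit], ind.genes])


def _vector_to_genome(vec: np.ndarray, n_features: int,
                      config: EvoConfig) -> Individual:
    mask = vec[:n_features] > 0.5
    family = "svm" if vec[n_features] > 0.5 else "random_forest"
    if family not in config.families:
        family = config.families[0]
    return Individual(mask=mask, family=family,
                      genes=vec[n_features + 1:].copy())


def _two_point_crossover(a: np.ndarray, b: np.ndarray,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = len(a)
    i, j = sorted(rng.choice(n + 1, size=2, replace=False))
    ca, cb = a.copy(), b.copy()
    ca[i:j], cb[i:j] = b[i:j], a[i:j]
    return ca, cb


def _arithmetic_crossover(a: np.ndarray, b: np.ndarray,
                          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    alpha = rng.random()
    return alpha * a + (1 - alpha) * b, alpha * b + (1 - alpha) * a


def _mutate(vec: np.ndarray, n_features: int, p: float,
            rng: np.random.Generator) -> np.ndarray:
    out = vec.copy()
    hit = rng.random(len(vec)) < p
    # binary part (mask + family bit): flip
    binary = np.arange(len(vec)) <= n_features
    flip = hit & binary
    out[flip] = 1.0 - (out[flip] > 0.5).astype(float)
    # real part: Gaussian jitter
    real = hit & ~binary
    out[real] += rng.normal(0.0, 0.25, size=int(real.sum()))
    out[n_features + 1] = np.clip(out[n_features + 1], 0.0, 1.0)
    return out


def _tournament(population: list[Individual], rng: np.random.Generator,
                size: int) -> Individual:
    picks = rng.integers(len(population), size=size)
    best = max(picks, key=lambda i: population[i].fitness)
    return population[best]


# -- main loop ---------------------------------------------------------------

@dataclass
class EvolveResult:
    front: list[Individual]
    history: pd.DataFrame
    population: list[Individual]
    config: EvoConfig


def evolve(X: np.ndarray, y: np.ndarray, config: EvoConfig,
           n_features: int | None = None) -> EvolveResult:
    """Generational loop with tournament selection, two-point crossover,
    per-gene mutation and Pareto-front elitism.

    ``history`` records per generation the best and mean scalar fitness and
    a convergence flag (mean within 5% of the best — diagnostic only; the
    loop always runs to ``max_generations``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    m = n_features or X.shape[1]
    rng = np.random.default_rng(config.seed)
    cache: dict[tuple, tuple[np.ndarray, MetricVector, float]] = {}

    def ensure_evaluated(ind: Individual) -> None:
        key = ind.genome_key()
        if key in cache:
            ind.objectives, ind.metrics, ind.fitness = cache[key]
            return
        evaluate(ind, X, y, config)
        cache[key] = (ind.objectives, ind.metrics, ind.fitness)

    population = [_random_individual(m, config, rng)
                  for _ in range(config.population_size)]
    for ind in population:
        ensure_evaluated(ind)

    records = []
    for gen in range(config.max_generations):
        front = pareto_front(population)
        fitness = np.array([ind.fitness for ind in population])
        best, mean = float(fitness.max()), float(fitness.mean())
        records.append({"generation": gen, "best_fitness": best,
                        "mean_fitness": mean,
                        "converged": bool(best > 0 and
                                          (best - mean) / best < 0.05),
                        "front_size": len(front)})

        elites = sorted(front, key=lambda i: (-i.fitness, i.n_features))
        elites = elites[:config.population_size]
        offspring: list[Individual] = []
        while len(elites) + len(offspring) < config.population_size:
            p1 = _tournament(population, rng, config.tournament_size)
            p2 = _tournament(population, rng, config.tournament_size)
            v1, v2 = _genome_to_vector(p1), _genome_to_vector(p2)
            if rng.random() < config.p_two_point_crossover:
                v1, v2 = _two_point_crossover(v1, v2, rng)
            if rng.random() < config.p_arithmetic_crossover:
                v1, v2 = _arithmetic_crossover(v1, v2, rng)
            for v in (v1, v2):
                if len(elites) + len(offspring) >= config.population_size:
                    break
                child = _vector_to_genome(
                    _mutate(v, m, config.p_mutation, rng), m, config)
                _repair(child, rng)
                offspring.append(child)
        population = elites + offspring
        for ind in population:
            ensure_evaluated(ind)

    front = pareto_front(population)
    history = pd.DataFrame.from_records(records)
    logger.info("evolution finished: %d generations, front size %d, "
                "best fitness %.3f", config.max_generations, len(front),
                max(ind.fitness for ind in front))
    return EvolveResult(front=front, history=history,
                        population=population, config=config)


def select_final(front: Sequence[Individual],
                 preference: str | int = "knee") -> Individual:
    """Pick the final model from a Pareto front.

    ``knee`` (default): maximum scalar fitness, ties broken towards fewer
    features; ``fewest_features``; ``max_accuracy``; or an explicit index.
    """
    front = list(front)
    if not front:
        raise ValueError("empty Pareto front")
    if isinstance(preference, int):
        return front[preference]
    if preference == "knee":
        return min(front, key=lambda i: (-i.fitness, i.n_features))
    if preference == "fewest_features":
        return min(front, key=lambda i: (i.n_features, -i.fitness))
    if preference == "max_accuracy":
        return min(front, key=lambda i: (-i.metrics.acc, i.n_features))
    raise ValueError(f"unknown preference {preference!r}")


def aggregate_runs(chosen: Sequence[Individual]) -> pd.DataFrame:
    """Mean ± SD of each rate metric over the final models of several runs."""
    rows = {name: [ind.metrics.rates()[i] for ind in chosen]
            for i, name in enumerate(("acc", "f1", "f2", "precision",
                                      "recall", "auc"))}
    frame = pd.DataFrame(rows)
    return pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=0)})
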