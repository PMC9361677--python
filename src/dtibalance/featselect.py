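"""Feature selection: genetic-algorithm mask search and booster importance.

The GA evolves binary column masks; fitness is the mean stratified-CV
accuracy of a small, fast tree ensemble restricted to the masked columns.
The booster route ranks columns by impurity-gain importance of a
gradient-boosted tree model and keeps the top k. Either mask then feeds
the full downstream benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class GAConfig:
    population: int = 50
    generations: int = 20
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # default 1/n_features
    fitness_folds: int = 3
    seed: int = 0
    elitism: int = 1
    tournament_size: int = 3

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0 <= self.crossover_rate <= 1:
            raise ValueError("crossover_rate must lie in [0, 1]")
        if self.mutation_rate is not None and not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.elitism < 0 or self.elitism >= self.population:
            raise ValueError("elitism must lie in [0, population)")


@dataclass(frozen=True)
class FeatureMask:
    bits: tuple[int, ...]
    fitness: float

    def __post_init__(self) -> None:
        if not any(self.bits):
            raise ValueError("mask must select at least one feature")

    @property
    def selected_indices(self) -> tuple[int, ...]:
        return tuple(i for i, b in enumerate(self.bits) if b)

    def apply(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features)[:, list(self.selected_indices)]


def _mask_fitness(
    features: np.ndarray, labels: np.ndarray, bits: np.ndarray,
    folds: int, seed: int,
) -> float:
    cols = np.nonzero(bits)[0]
    x = features[:, cols]
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in splitter.split(x, labels):
        clf = ExtraTreesClassifier(n_estimators=20, random_state=seed)
        clf.fit(x[train_idx], labels[train_idx])
        accs.append(float((clf.predict(x[test_idx]) == labels[test_idx]).mean()))
    return float(np.mean(accs))


def _mask_key(bits: np.ndarray) -> tuple[int, ...]:
    # Tie-break: prefer the mask whose selected-index tuple sorts first,
    # then fewer features.
    idx = tuple(np.nonzero(bits)[0].tolist())
    return (idx, len(idx))


def ga_select(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: GAConfig = GAConfig(),
    return_history: bool = False,
) -> FeatureMask | tuple[FeatureMask, list[float]]:
    """Best feature mask found by a generational GA.

    Tournament selection, uniform crossover, per-bit mutation (default rate
    1/n_features) and elitism; deterministic for a given seed. Ties in
    fitness resolve toward the mask with the earliest selected columns.
    With ``return_history`` the best-so-far fitness after each generation
    is returned as well (non-decreasing under elitism).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 feature columns")
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    n = x.shape[1]
    mut = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / n
    rng = np.random.default_rng(cfg.seed)

    def fix(bits: np.ndarray) -> np.ndarray:
        if not bits.any():
            bits[rng.integers(n)] = 1
        return bits

    # Deterministic anchors (first-column-only, all-ones) plus random masks.
    population = [np.eye(1, n, 0, dtype=int).ravel(), np.ones(n, dtype=int)]
    while len(population) < cfg.population:
        population.append(fix((rng.random(n) < 0.5).astype(int)))
    population = population[: cfg.population]

    cache: dict[tuple[int, ...], float] = {}

    def fitness(bits: np.ndarray) -> float:
        key = tuple(bits.tolist())
        if key not in cache:
            cache[key] = _mask_fitness(x, y, bits, cfg.fitness_folds, cfg.seed)
        return cache[key]

    def better(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        fa, fb = fitness(a), fitness(b)
        if fa != fb:
            return a if fa > fb else b
        return a if _mask_key(a) <= _mask_key(b) else b

    best = population[0]
    for cand in population[1:]:
        best = better(best, cand)

    history: list[float] = [fitness(best)]
    for _ in range(cfg.generations):
        scored = sorted(
            population,
            key=lambda b: (-fitness(b), _mask_key(b)),
        )
        next_pop = [b.copy() for b in scored[: cfg.elitism]]
        while len(next_pop) < cfg.population:
            parents = []
            for _ in range(2):
                t_size = min(cfg.tournament_size, len(population))
                entrants = rng.choice(len(population), t_size, replace=False)
                winner = population[entrants[0]]
                for j in entrants[1:]:
                    winner = better(winner, population[j])
                parents.append(winner)
            a, b = parents[0].copy(), parents[1].copy()
            if rng.random() < cfg.crossover_rate:
                swap = rng.random(n) < 0.5
                a[swap], b[swap] = b[swap], a[swap].copy()
            for child in (a, b):
                flip = rng.random(n) < mut
                child[flip] = 1 - child[flip]
                next_pop.append(fix(child))
                if len(next_pop) >= cfg.population:
                    break
        population = next_pop
        for cand in population:
            best = better(best, cand)
        history.append(fitness(best))

    mask = FeatureMask(tuple(best.tolist()), fitness(best))
    return (mask, history) if return_history else mask


def booster_importance_select(
    features: np.ndarray,
    labels: np.ndarray,
    top_k: int,
    seed: int = 0,
) -> FeatureMask:
    """Mask of the top-k columns by gradient-boosting gain importance."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if top_k > x.shape[1]:
        raise ValueError(f"top_k={top_k} exceeds {x.shape[1]} feature columns")
    model = GradientBoostingClassifier(
        max_depth=3, n_estimators=50, random_state=seed
    )
    model.fit(x, y)
    importances = model.feature_importances_
    # Stable order: importance descending, then column index ascending.
    ranked = np.lexsort((np.arange(x.shape[1]), -importances))
    chosen = set(ranked[:top_k].tolist())
    bits = tuple(1 if i in chosen else 0 for i in range(x.shape[1]))
    fitness = float(importances[list(chosen)].sum())
    return FeatureMask(bits, fitness)
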