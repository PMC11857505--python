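"""Genetic-algorithm hyperparameter tuning for the RFE + random-forest
classifier.

Each individual is one :class:`~sfmetab.model_select.HyperParams` set (the
RFE retained-set size plus six forest hyperparameters) drawn from per-field
value grids. Fitness is

    Fitness = MCC¹⁵ · N_RFE²     (clamped to 0 for negative MCC)

where MCC is the LOOCV score of the corresponding model. The 15th power
makes an MCC-1.0 model weigh about five times an MCC-0.9 one
((1/0.9)¹⁵ ≈ 4.87), while the quadratic term prefers models that keep more
bins. Parents are drawn with probability proportional to fitness; crossover
exchanges exactly two hyperparameter slots; a point mutation reassigns one
slot with probability P_mut; the two best members are preserved both as a
mutable copy and as a pristine duplicate, so the best fitness never
decreases.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from sfmetab.core_io import BinMatrix
from sfmetab.model_select import HyperParams, rf_loocv, rfe_ranking, rfe_select

logger = logging.getLogger(__name__)

FIELDS = ("n_rfe", "n_est", "max_depth", "min_samples_split",
          "min_samples_leaf", "max_features_rule", "criterion")


@dataclass(frozen=True)
class SearchSpace:
    """Ordered value grids, one per hyperparameter field."""

    grids: tuple[tuple, ...]

    def __post_init__(self) -> None:
        if len(self.grids) != len(FIELDS):
            raise ValueError(f"need one grid per field ({len(FIELDS)})")
        if any(len(g) == 0 for g in self.grids):
            raise ValueError("every grid must be non-empty")

    @classmethod
    def from_dict(cls, grids: dict[str, list]) -> "SearchSpace":
        return cls(grids=tuple(tuple(grids[f]) for f in FIELDS))

    def to_dict(self) -> dict[str, list]:
        return {f: list(g) for f, g in zip(FIELDS, self.grids)}

    @property
    def cardinality(self) -> int:
        out = 1
        for g in self.grids:
            out *= len(g)
        return out

    def contains(self, hp: HyperParams) -> bool:
        return all(v in g for v, g in zip(hp.as_tuple(), self.grids))

    def sample(self, rng: np.random.Generator) -> HyperParams:
        values = [g[rng.integers(len(g))] for g in self.grids]
        return HyperParams(**dict(zip(FIELDS, values)))


def default_search_space() -> SearchSpace:
    """Default grids: >12 million combinations, containing the reported
    optimum (N_RFE=50, 100 trees, depth 6, split 10, leaf 6, ⌊log₂⌋ feature
    rule, log_loss criterion). The grids are this package's own choice, not
    a reconstruction of any particular study's."""
    return SearchSpace.from_dict({
        "n_rfe": list(range(5, 200, 5)),
        "n_est": [25, 50, 100, 200, 400, 800, 1600],
        "max_depth": list(range(2, 13)),
        "min_samples_split": list(range(2, 25)),
        "min_samples_leaf": list(range(1, 13)),
        "max_features_rule": ["log2", "sqrt", 3, 5, 10],
        "criterion": ["gini", "entropy", "log_loss"],
    })


def reduced_search_space() -> SearchSpace:
    """Small grids for quick runs and tests: modest forests and a single
    split criterion, sized so a 20-member population revisits combinations
    often (cheap cached evaluations)."""
    return SearchSpace.from_dict({
        "n_rfe": [20, 50, 80],
        "n_est": [25, 50],
        "max_depth": [3, 6],
        "min_samples_split": [2, 10],
        "min_samples_leaf": [1, 6],
        "max_features_rule": ["log2", "sqrt"],
        "criterion": ["log_loss"],
    })


@dataclass(frozen=True)
class GAConfig:
    n_pop: int = 100
    n_par: int = 2          # parents drawn per crossover
    n_cross: int = 2        # hyperparameter slots exchanged
    n_elite: int = 2
    n_mut: int = 1          # slots touched per point mutation
    p_mut: float = 0.90
    n_gen: int = 35
    seed: int = 0
    mutate_elite_copies: bool = True   # the non-pristine elite copies pass through mutation

    def __post_init__(self) -> None:
        if self.n_pop - 2 * self.n_elite <= 0:
            raise ValueError("n_pop must exceed 2*n_elite")
        if not 0.0 <= self.p_mut <= 1.0:
            raise ValueError("p_mut must lie in [0,1]")


@dataclass
class GAState:
    population: list[HyperParams]
    fitnesses: list[float]
    generation: int = 0
    history: list[dict] = field(default_factory=list)
    best: HyperParams | None = None
    best_fitness: float = -np.inf
    best_mcc: float = 0.0
    cache: dict[tuple, tuple[float, float]] = field(default_factory=dict)  # hp -> (mcc, fitness)

    @property
    def elites(self) -> list[HyperParams]:
        order = sorted(range(len(self.population)), key=lambda i: -self.fitnesses[i])
        return [self.population[i] for i in order]


def fitness(mcc_value: float, n_rfe: int) -> float:
    """Eq.-style fitness MCC¹⁵ · N_RFE², clamped to 0 below MCC 0."""
    if not -1.0 <= mcc_value <= 1.0:
        raise ValueError("mcc must lie in [-1, 1]")
    if n_rfe < 1:
        raise ValueError("n_rfe must be >= 1")
    return max(mcc_value, 0.0) ** 15 * n_rfe ** 2


def selection_weights(fitnesses) -> np.ndarray:
    """Fitness-proportional selection probabilities; uniform when every
    fitness is zero."""
    f = np.asarray(fitnesses, dtype=float)
    if np.any(f < 0):
        raise ValueError("fitnesses must be nonnegative")
    total = f.sum()
    if total == 0:
        return np.full(f.size, 1.0 / f.size)
    return f / total


def crossover(parent_a: HyperParams, parent_b: HyperParams,
              rng: np.random.Generator, n_cross: int = 2) -> tuple[HyperParams, HyperParams]:
    """Swap the values of exactly ``n_cross`` distinct hyperparameter slots
    (chosen uniformly without replacement) between the parents."""
    slots = rng.choice(len(FIELDS), size=n_cross, replace=False)
    a, b = dict(zip(FIELDS, parent_a.as_tuple())), dict(zip(FIELDS, parent_b.as_tuple()))
    for s in slots:
        f = FIELDS[s]
        a[f], b[f] = b[f], a[f]
    return HyperParams(**a), HyperParams(**b)


def mutate(individual: HyperParams, rng: np.random.Generator, space: SearchSpace,
           p_mut: float = 0.90) -> HyperParams:
    """With probability ``p_mut``, reassign one uniformly chosen slot to a
    uniformly chosen *different* grid value; slots whose grid has a single
    value are resampled."""
    if rng.random() >= p_mut:
        return individual
    mutable = [s for s, g in enumerate(space.grids) if len(g) > 1]
    if not mutable:
        return individual
    s = mutable[rng.integers(len(mutable))]
    current = individual.as_tuple()[s]
    choices = [v for v in space.grids[s] if v != current]
    value = choices[rng.integers(len(choices))]
    return replace(individual, **{FIELDS[s]: value})


class MccEvaluator:
    """Maps a hyperparameter set to (LOOCV MCC, fitness) on one scaled
    matrix of non-perfect bins.

    The full SVM-RFE elimination order is computed once and shared by every
    retained-set size; the forest seed for an individual is derived
    deterministically from the master seed and the hyperparameter tuple, so
    a fitness evaluation is reproducible and cacheable.
    """

    def __init__(self, matrix: BinMatrix, seed: int = 0):
        self.matrix = matrix
        self.seed = seed
        self._ranking = rfe_ranking(matrix)

    def _rf_seed(self, hp: HyperParams) -> int:
        digest = zlib.crc32(repr(hp.as_tuple()).encode())
        return (self.seed * 1000003 + digest) % (2 ** 31)

    def __call__(self, hp: HyperParams) -> tuple[float, float]:
        n_keep = min(hp.n_rfe, self.matrix.n_bins)
        retained = rfe_select(self.matrix, n_keep, ranking=self._ranking)
        sub = self.matrix.select_bins(retained)
        metrics = rf_loocv(sub, hp, seed=self._rf_seed(hp))
        return metrics.mcc, fitness(metrics.mcc, n_keep)


def _evaluate(state: GAState, evaluator) -> None:
    state.fitnesses = []
    for hp in state.population:
        key = hp.as_tuple()
        if key not in state.cache:
            try:
                state.cache[key] = evaluator(hp)
            except Exception as exc:  # degenerate individual: fitness 0
                logger.warning("evaluation failed for %s: %s", hp, exc)
                state.cache[key] = (0.0, 0.0)
        m, f = state.cache[key]
        state.fitnesses.append(f)
        if f > state.best_fitness:
            state.best, state.best_fitness, state.best_mcc = hp, f, m
    state.history.append({
        "generation": state.generation,
        "best": float(np.max(state.fitnesses)),
        "mean": float(np.mean(state.fitnesses)),
        "best_ever": float(state.best_fitness),
    })


def next_generation(state: GAState, evaluator, rng: np.random.Generator,
                    config: GAConfig, space: SearchSpace) -> GAState:
    """One generational step: fitness-weighted parent selection and
    crossover produce ``n_pop − 2·n_elite`` offspring; those plus one copy
    of each elite pass through point mutation; the pristine elite
    duplicates top the population back up to ``n_pop``."""
    weights = selection_weights(state.fitnesses)
    n_new = config.n_pop - 2 * config.n_elite
    offspring: list[HyperParams] = []
    while len(offspring) < n_new:
        i, j = rng.choice(len(state.population), size=config.n_par, replace=True, p=weights)[:2]
        c1, c2 = crossover(state.population[i], state.population[j], rng, config.n_cross)
        offspring.extend([c1, c2])
    offspring = offspring[:n_new]

    elites = state.elites[:config.n_elite]
    pool = offspring + list(elites)
    if config.mutate_elite_copies:
        pool = [mutate(hp, rng, space, config.p_mut) for hp in pool]
    else:
        pool = [mutate(hp, rng, space, config.p_mut) for hp in offspring] + list(elites)
    population = pool + list(elites)          # pristine duplicates
    assert len(population) == config.n_pop

    new_state = GAState(population=population, fitnesses=[],
                        generation=state.generation + 1, history=state.history,
                        best=state.best, best_fitness=state.best_fitness,
                        best_mcc=state.best_mcc, cache=state.cache)
    _evaluate(new_state, evaluator)
    return new_state


@dataclass
class GAResult:
    best: HyperParams
    best_fitness: float
    best_mcc: float
    history: list[dict]
    n_evaluated: int
    state: GAState


def run_ga(matrix: BinMatrix, space: SearchSpace | None = None,
           config: GAConfig = GAConfig(), evaluator=None) -> GAResult:
    """Evolve hyperparameter populations on a scaled matrix of non-perfect
    bins.

    The initial population is sampled uniformly from the space; after
    ``n_gen`` generations the best-ever individual, the per-generation
    best/mean fitness trace, and the count of unique hyperparameter sets
    evaluated are returned. Identical seeds give identical trajectories.
    """
    space = space or default_search_space()
    evaluator = evaluator or MccEvaluator(matrix, seed=config.seed)
    rng = np.random.default_rng(config.seed)
    state = GAState(population=[space.sample(rng) for _ in range(config.n_pop)], fitnesses=[])
    _evaluate(state, evaluator)
    for _ in range(config.n_gen):
        state = next_generation(state, evaluator, rng, config, space)
    return GAResult(best=state.best, best_fitness=state.best_fitness,
                    best_mcc=state.best_mcc, history=state.history,
                    n_evaluated=len(state.cache), state=state)
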