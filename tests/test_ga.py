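import numpy as np
import pytest

from sfmetab.ga import (
    FIELDS,
    GAConfig,
    GAState,
    SearchSpace,
    _evaluate,
    crossover,
    default_search_space,
    fitness,
    mutate,
    next_generation,
    reduced_search_space,
    run_ga,
    selection_weights,
)
from sfmetab.model_select import HyperParams

OPTIMUM = HyperParams(n_rfe=50, n_est=100, max_depth=6, min_samples_split=10,
                      min_samples_leaf=6, max_features_rule="log2", criterion="log_loss")


class ToyEvaluator:
    """Deterministic surrogate fitness: peaks at the reference optimum.

    Lets GA mechanics be tested without training forests."""

    def __init__(self):
        self.calls = 0

    def __call__(self, hp: HyperParams):
        self.calls += 1
        target = OPTIMUM.as_tuple()
        matches = sum(a == b for a, b in zip(hp.as_tuple(), target))
        m = matches / len(target)
        return m, fitness(m, hp.n_rfe)


def test_fitness_values():
    assert fitness(1.0, 50) == pytest.approx(2500.0)
    assert fitness(0.9, 50) == pytest.approx(0.9 ** 15 * 2500, rel=1e-12)
    assert fitness(-0.5, 50) == 0.0


def test_fitness_weighting_ratio_about_five():
    ratio = fitness(1.0, 50) / fitness(0.9, 50)
    assert ratio == pytest.approx((1 / 0.9) ** 15)
    assert round(ratio) == 5


def test_selection_weights_proportional_and_normalized():
    np.testing.assert_allclose(selection_weights([1.0, 1.0, 2.0]), [0.25, 0.25, 0.5])
    np.testing.assert_allclose(selection_weights([0.0, 0.0]), [0.5, 0.5])
    rng = np.random.default_rng(0)
    w = selection_weights(rng.random(50))
    assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_default_space_size_and_optimum_membership():
    space = default_search_space()
    assert space.cardinality > 6_700_000
    assert space.contains(OPTIMUM)
    assert reduced_search_space().cardinality < 1000


def test_crossover_swaps_exactly_two_slots():
    space = default_search_space()
    rng = np.random.default_rng(1)
    a = HyperParams(n_rfe=10, n_est=25, max_depth=2, min_samples_split=2,
                    min_samples_leaf=1, max_features_rule="sqrt", criterion="gini")
    b = OPTIMUM
    for _ in range(100):
        c1, c2 = crossover(a, b, rng)
        diff = sum(x != y for x, y in zip(c1.as_tuple(), a.as_tuple()))
        assert diff == 2
        # per-slot multiset conservation across the pair
        for s in range(len(FIELDS)):
            assert {c1.as_tuple()[s], c2.as_tuple()[s]} == {a.as_tuple()[s], b.as_tuple()[s]}
    same1, same2 = crossover(a, a, rng)
    assert same1 == a and same2 == a


def test_mutate_probability_and_hamming_distance():
    space = default_search_space()
    rng = np.random.default_rng(2)
    changed = 0
    for _ in range(1000):
        out = mutate(OPTIMUM, rng, space, p_mut=0.9)
        diff = sum(x != y for x, y in zip(out.as_tuple(), OPTIMUM.as_tuple()))
        assert diff in (0, 1)
        changed += diff
    assert changed / 1000 == pytest.approx(0.9, abs=0.03)
    assert mutate(OPTIMUM, rng, space, p_mut=0.0) == OPTIMUM
    for _ in range(50):
        out = mutate(OPTIMUM, rng, space, p_mut=1.0)
        assert sum(x != y for x, y in zip(out.as_tuple(), OPTIMUM.as_tuple())) == 1


def test_generation_bookkeeping_pop100():
    """With N_pop=100 and N_elite=2 a generation creates exactly 96 new
    members and conserves the population size."""
    space = reduced_search_space()
    config = GAConfig(n_pop=100, n_elite=2, n_gen=1, seed=0)
    assert config.n_pop - 2 * config.n_elite == 96
    rng = np.random.default_rng(0)
    evaluator = ToyEvaluator()
    state = GAState(population=[space.sample(rng) for _ in range(100)], fitnesses=[])
    _evaluate(state, evaluator)
    new = next_generation(state, evaluator, rng, config, space)
    assert len(new.population) == 100
    elites = state.elites[:2]
    assert new.population[-2:] == elites            # pristine duplicates


def test_best_fitness_monotone_and_deterministic():
    space = reduced_search_space()
    config = GAConfig(n_pop=20, n_gen=6, seed=4)
    r1 = run_ga(matrix=None, space=space, config=config, evaluator=ToyEvaluator())
    r2 = run_ga(matrix=None, space=space, config=config, evaluator=ToyEvaluator())
    trace = [h["best_ever"] for h in r1.history]
    assert trace == sorted(trace)
    assert r1.history == r2.history
    assert r1.best == r2.best


def test_zero_generations_returns_best_of_initial_population():
    space = reduced_search_space()
    result = run_ga(matrix=None, space=space,
                    config=GAConfig(n_pop=20, n_gen=0, seed=3), evaluator=ToyEvaluator())
    assert len(result.history) == 1
    assert result.best_fitness == result.history[0]["best"]


def test_ga_beats_random_search_on_toy_landscape():
    """GA best fitness reaches the 99th percentile of 500 random draws."""
    space = default_search_space()
    config = GAConfig(n_pop=30, n_gen=10, seed=8)
    result = run_ga(matrix=None, space=space, config=config, evaluator=ToyEvaluator())
    rng = np.random.default_rng(99)
    evaluator = ToyEvaluator()
    draws = sorted(evaluator(space.sample(rng))[1] for _ in range(500))
    assert result.best_fitness >= draws[int(0.99 * 500)]


def test_failed_evaluation_scores_zero():
    class Exploding:
        def __call__(self, hp):
            raise RuntimeError("boom")
    space = reduced_search_space()
    result = run_ga(matrix=None, space=space,
                    config=GAConfig(n_pop=8, n_elite=1, n_gen=1, seed=0),
                    evaluator=Exploding())
    assert result.best_fitness == 0.0


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        GAConfig(n_pop=4, n_elite=2)
    with pytest.raises(ValueError):
        GAConfig(p_mut=1.5)
    with pytest.raises(ValueError):
        fitness(1.2, 50)


def test_search_space_round_trip_json():
    space = default_search_space()
    assert SearchSpace.from_dict(space.to_dict()) == space
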