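import itertools
import json
from math import factorial

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier

from sfmetab import pipeline
from sfmetab.attribution import (
    MarkerComparison,
    compare_selections,
    rank_attributions,
    shapley_attribution,
    tree_shap_values,
)
from sfmetab.core_io import BinInfo
from sfmetab.ga import GAConfig, reduced_search_space
from sfmetab.model_select import HyperParams, fit_final_forest, rfe_select
from sfmetab.plsda import RankedBin, fit_plsda, rank_bins
from sfmetab.preprocessing import normalize
from sfmetab.synthetic import SimulationConfig, simulate
from conftest import make_matrix


# --- independent oracle: conditional expectation by tree traversal + subset
# enumeration over every feature -------------------------------------------

def expected_value(tree, x, coalition):
    def rec(node):
        if tree.children_left[node] == -1:
            v = tree.value[node].ravel()
            return v[1] / v.sum()
        f = tree.feature[node]
        left, right = tree.children_left[node], tree.children_right[node]
        if f in coalition:
            return rec(left) if x[f] <= tree.threshold[node] else rec(right)
        w = tree.weighted_n_node_samples
        return (w[left] * rec(left) + w[right] * rec(right)) / w[node]
    return rec(0)


def brute_force_shapley(forest, x, n_features):
    phi = np.zeros(n_features)
    for est in forest.estimators_:
        t = est.tree_
        for i in range(n_features):
            rest = [j for j in range(n_features) if j != i]
            for r in range(n_features):
                for S in itertools.combinations(rest, r):
                    w = factorial(len(S)) * factorial(n_features - len(S) - 1) / factorial(n_features)
                    phi[i] += w * (expected_value(t, x, set(S) | {i}) - expected_value(t, x, set(S)))
    return phi / len(forest.estimators_)


def test_matches_enumeration_oracle_small_forest():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 4))
    y = (X[:, 0] + 0.5 * X[:, 1] - 0.3 * X[:, 2] + rng.normal(0, 0.5, 30) > 0).astype(int)
    forest = RandomForestClassifier(n_estimators=15, max_depth=2, random_state=0).fit(X, y)
    values, base = tree_shap_values(forest, X[:5])
    for i in range(5):
        oracle = brute_force_shapley(forest, X[i], 4)
        np.testing.assert_allclose(values[i], oracle, atol=1e-6)


def test_local_accuracy_on_synthetic_run(small_dataset):
    m = normalize(small_dataset.matrix, "minmax")
    sub = m.select_bins(rfe_select(m, 10))
    forest = fit_final_forest(sub, HyperParams(n_rfe=10, n_est=50), seed=0)
    result = shapley_attribution(forest, sub)
    predicted = forest.predict_proba(sub.values)[:, 1]
    np.testing.assert_allclose(result.base_value + result.shap_values.sum(axis=1),
                               predicted, atol=1e-6)


def test_constant_model_attributes_nothing():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(20, 3))
    y = np.array([0] * 10 + [1] * 10)
    # depth-0 behaviour: min_samples_leaf equal to n forces a single leaf
    forest = RandomForestClassifier(n_estimators=5, min_samples_leaf=20,
                                    random_state=0).fit(X, y)
    values, base = tree_shap_values(forest, X)
    np.testing.assert_allclose(values, 0.0, atol=1e-12)


def test_symmetric_and_function_shares_credit_equally():
    """Symmetry axiom: for a balanced conjunction (y = x0 AND x1) learned by
    a depth-2 tree, both features receive identical attributions even though
    the tree tests them in sequence."""
    X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]] * 5)
    y = (X[:, 0] * X[:, 1] > 0).astype(int)
    from sklearn.tree import DecisionTreeClassifier
    tree = DecisionTreeClassifier(max_depth=2, random_state=0).fit(X, y)
    values, base = tree_shap_values(tree, np.array([[1.0, 1.0], [0.0, 0.0]]))
    assert values[0, 0] == pytest.approx(values[0, 1], abs=1e-12)
    assert values[1, 0] == pytest.approx(values[1, 1], abs=1e-12)
    # the AND point: base 1/4, output 1, each feature lifts 3/8
    assert base == pytest.approx(0.25)
    assert values[0, 0] == pytest.approx(0.375)


def test_ranking_completeness_and_order(small_dataset):
    m = normalize(small_dataset.matrix, "minmax")
    sub = m.select_bins(rfe_select(m, 10))
    forest = fit_final_forest(sub, HyperParams(n_rfe=10, n_est=50), seed=0)
    result = shapley_attribution(forest, sub)
    full = rank_attributions(result, k=10)
    assert {r.bin.bin_id for r in full} == set(sub.bin_ids)
    scores = [r.mean_abs_shap for r in full]
    assert scores == sorted(scores, reverse=True)
    with pytest.raises(ValueError):
        rank_attributions(result, k=11)


def test_directions_match_planted_effects():
    """Attribution direction agrees with the planted effect direction for
    top-ranked informative bins."""
    agree = total = 0
    for seed in range(5):
        ds = simulate(SimulationConfig(seed=seed))
        m = normalize(ds.matrix, "minmax")
        keep = [b for b in m.bin_ids if ds.truth[b] != "perfect"]
        sub = m.select_bins(rfe_select(m.select_bins(keep), 50))
        forest = fit_final_forest(sub, HyperParams(), seed=seed)
        result = shapley_attribution(forest, sub)
        for r in rank_attributions(result, 10):
            if ds.truth[r.bin.bin_id] == "informative" and r.direction != 0:
                total += 1
                agree += r.direction == ds.directions[r.bin.bin_id]
    assert total > 0
    assert agree / total >= 0.95


def _plsda_like(oa_names, ra_names):
    class R:
        pass
    r = R()
    r.ranking_OA = [RankedBin(BinInfo(f"{n} [1.0]", n, 1.0), -0.1) for n in oa_names]
    r.ranking_RA = [RankedBin(BinInfo(f"{n} [2.0]", n, 2.0), 0.1) for n in ra_names]
    return r


def _ml_like(oa_names, ra_names):
    from sfmetab.attribution import RankedAttribution
    out = [RankedAttribution(BinInfo(f"{n} [3.0]", n, 3.0), 0.5, -1) for n in oa_names]
    out += [RankedAttribution(BinInfo(f"{n} [4.0]", n, 4.0), 0.5, +1) for n in ra_names]
    return out


def test_compare_identical_selections():
    plsda = _plsda_like(["glc", "gln"], ["pro", "ace"])
    ml = _ml_like(["glc", "gln"], ["pro", "ace"])
    c = compare_selections(plsda, ml)
    assert c.overlap_OA == {"glc", "gln"} and c.overlap_RA == {"pro", "ace"}
    assert not (c.unique_ml_OA | c.unique_plsda_OA | c.unique_ml_RA | c.unique_plsda_RA)
    assert c.ambiguous == set()


def test_cross_disease_metabolite_is_ambiguous():
    # lysine: OA by one method, RA by the other
    c = compare_selections(_plsda_like(["lys", "glc"], ["pro"]),
                           _ml_like(["glc"], ["lys", "ace"]))
    assert "lys" in c.ambiguous


def test_compare_symmetric_under_method_swap():
    plsda = _plsda_like(["a", "b"], ["c"])
    ml = _ml_like(["b", "d"], ["a"])
    c1 = compare_selections(plsda, ml)
    c2 = MarkerComparison(set_plsda_OA={"b", "d"}, set_plsda_RA={"a"},
                          set_ml_OA={"a", "b"}, set_ml_RA={"c"})
    assert c1.ambiguous == c2.ambiguous
    assert c1.overlap_OA == c2.overlap_OA


@pytest.fixture(scope="module")
def small_pipeline_run():
    ds = simulate(SimulationConfig(n_bins=40, n_perfect=2, n_informative=10, seed=11))
    config = GAConfig(n_pop=10, n_elite=1, n_gen=2, seed=11)
    return ds, pipeline.run_pipeline(ds.matrix, seed=11, space=reduced_search_space(),
                                     ga_config=config, top_k=10)


def test_run_report_schema_and_bookkeeping(small_pipeline_run):
    ds, result = small_pipeline_run
    summary = result.summary
    for key in ("normalization", "stump_screen", "best_params", "loocv",
                "attribution", "marker_comparison", "seeds"):
        assert key in summary
    assert len(summary["loocv"]["predictions"]) == ds.matrix.n_samples
    assert summary["stump_screen"]["perfect_bins"] == sorted(ds.bins_of("perfect"))
    json.dumps(summary)   # fully serializable


def test_run_report_reruns_byte_identical(small_pipeline_run):
    ds, result = small_pipeline_run
    config = GAConfig(n_pop=10, n_elite=1, n_gen=2, seed=11)
    again = pipeline.run_pipeline(ds.matrix, seed=11, space=reduced_search_space(),
                                  ga_config=config, top_k=10)
    assert json.dumps(result.summary, sort_keys=True) == json.dumps(again.summary, sort_keys=True)
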