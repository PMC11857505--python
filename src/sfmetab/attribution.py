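"""Exact Shapley-value attribution for tree ensembles, top-bin ranking, and
the PLS-DA-vs-ML marker comparison.

The explained output is the forest's RA (class-1) probability, so a
positive attribution pushes a patient toward the RA diagnosis and a
negative one toward OA.

Attributions use the path-dependent conditional expectation: when a
coalition omits a split feature, the walk follows both children weighted by
their training cover (weighted node sample counts). For one tree this value
function decomposes additively over leaves, and each leaf term depends only
on the distinct features along its root path — so the Shapley value is
computed exactly, leaf by leaf, with an elementary-symmetric-polynomial
recursion over the path features (no sampling, no approximation). Ensemble
attributions are the average over trees; local accuracy
(base + Σ attributions = predicted probability) holds to numerical
precision for every sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np

from sfmetab.core_io import BinInfo, BinMatrix


@dataclass
class AttributionResult:
    shap_values: np.ndarray             # n_samples × n_bins, probability scale
    base_value: float
    bins: list[BinInfo]
    scale: str = "probability"          # the explained model output
    ranking: list["RankedAttribution"] = field(default_factory=list)
    direction: dict[str, int] = field(default_factory=dict)  # +1 promotes RA, -1 promotes OA

    def mean_abs(self) -> np.ndarray:
        return np.abs(self.shap_values).mean(axis=0)


@dataclass
class RankedAttribution:
    bin: BinInfo
    mean_abs_shap: float
    direction: int                      # +1 promotes RA, -1 promotes OA


@dataclass
class MarkerComparison:
    set_plsda_OA: set[str]
    set_plsda_RA: set[str]
    set_ml_OA: set[str]
    set_ml_RA: set[str]
    overlap_OA: set[str] = field(init=False)
    overlap_RA: set[str] = field(init=False)
    unique_plsda_OA: set[str] = field(init=False)
    unique_plsda_RA: set[str] = field(init=False)
    unique_ml_OA: set[str] = field(init=False)
    unique_ml_RA: set[str] = field(init=False)
    ambiguous: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.overlap_OA = self.set_plsda_OA & self.set_ml_OA
        self.overlap_RA = self.set_plsda_RA & self.set_ml_RA
        self.unique_plsda_OA = self.set_plsda_OA - self.set_ml_OA
        self.unique_plsda_RA = self.set_plsda_RA - self.set_ml_RA
        self.unique_ml_OA = self.set_ml_OA - self.set_plsda_OA
        self.unique_ml_RA = self.set_ml_RA - self.set_plsda_RA
        self.ambiguous = (self.set_plsda_OA | self.set_ml_OA) & (self.set_plsda_RA | self.set_ml_RA)


# ---------------------------------------------------------------------------
# exact tree Shapley

@dataclass
class _Leaf:
    features: list[int]                 # distinct split features on the root path
    constraints: list[list[tuple[float, bool]]]  # per feature: (threshold, goes_left)
    betas: np.ndarray                   # per feature: product of cover ratios
    value: float                        # class-1 probability at the leaf


def _tree_leaves(tree, class1_index: int) -> list[_Leaf]:
    left, right = tree.children_left, tree.children_right
    feat, thr = tree.feature, tree.threshold
    cover = tree.weighted_n_node_samples
    leaves: list[_Leaf] = []

    def walk(node: int, path: list[tuple[int, float, bool, float]]) -> None:
        if left[node] == -1:            # leaf
            val = np.asarray(tree.value[node]).ravel()
            prob = float(val[class1_index] / val.sum())
            feats: dict[int, tuple[list[tuple[float, bool]], float]] = {}
            for f, t, goes_left, ratio in path:
                cons, beta = feats.get(f, ([], 1.0))
                cons.append((t, goes_left))
                feats[f] = (cons, beta * ratio)
            keys = sorted(feats)
            leaves.append(_Leaf(
                features=keys,
                constraints=[feats[f][0] for f in keys],
                betas=np.array([feats[f][1] for f in keys]),
                value=prob,
            ))
            return
        for child, goes_left in ((left[node], True), (right[node], False)):
            ratio = cover[child] / cover[node]
            walk(child, path + [(int(feat[node]), float(thr[node]), goes_left, float(ratio))])

    walk(0, [])
    return leaves


def _shapley_weights(p: int) -> np.ndarray:
    """w[s] = s!(p−s−1)!/p! for s = 0..p−1."""
    fp = factorial(p)
    return np.array([factorial(s) * factorial(p - s - 1) / fp for s in range(p)])


def _elementary_symmetric(values: np.ndarray) -> np.ndarray:
    """e_0..e_m of the given values."""
    e = np.zeros(values.size + 1)
    e[0] = 1.0
    for v in values:
        e[1:] = e[1:] + v * e[:-1]
    return e


def _leaf_shapley(leaf: _Leaf, alphas: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley contributions of one leaf's term for one sample.

    ``alphas[j]`` is 1 when the sample satisfies every path constraint of
    the leaf's j-th feature, else 0. Returns (per-feature contributions,
    leaf contribution to the base value).
    """
    p = len(leaf.features)
    w = _shapley_weights(p)
    betas = leaf.betas
    base = leaf.value * float(np.prod(betas))
    phi = np.zeros(p)
    for i in range(p):
        diff = alphas[i] - betas[i]
        if diff == 0.0:
            continue
        others = [j for j in range(p) if j != i]
        in_pool = [j for j in others if alphas[j] == 1.0]   # may join the coalition
        out = [j for j in others if alphas[j] == 0.0]       # always contribute beta
        c_out = float(np.prod(betas[out])) if out else 1.0
        if in_pool:
            e = _elementary_symmetric(betas[np.array(in_pool)])
            a = len(in_pool)
            inner = sum(w[k] * e[a - k] for k in range(a + 1))
        else:
            inner = w[0]
        phi[i] = leaf.value * diff * c_out * inner
    return phi, base


def _sample_alphas(leaf: _Leaf, X: np.ndarray) -> np.ndarray:
    """n_samples × n_path_features indicator: does the sample satisfy every
    constraint the leaf's path places on that feature?"""
    n = X.shape[0]
    alphas = np.ones((n, len(leaf.features)))
    for j, (f, cons) in enumerate(zip(leaf.features, leaf.constraints)):
        ok = np.ones(n, dtype=bool)
        for t, goes_left in cons:
            ok &= (X[:, f] <= t) if goes_left else (X[:, f] > t)
        alphas[:, j] = ok
    return alphas


def tree_shap_values(forest, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact path-dependent Shapley attributions of the forest's class-1
    probability for every row of ``X``. Returns (n × p attributions, base)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    class1 = int(np.flatnonzero(forest.classes_ == 1)[0])
    total = np.zeros((n, p))
    base = 0.0
    estimators = getattr(forest, "estimators_", [forest])
    for est in estimators:
        leaves = _tree_leaves(est.tree_, class1)
        tree_base = 0.0
        for leaf in leaves:
            alphas = _sample_alphas(leaf, X)
            # samples sharing an alpha pattern share their contributions
            patterns, inverse = np.unique(alphas, axis=0, return_inverse=True)
            for g, pattern in enumerate(patterns):
                phi, leaf_base = _leaf_shapley(leaf, pattern)
                rows = np.flatnonzero(inverse == g)
                for j, f in enumerate(leaf.features):
                    total[rows, f] += phi[j]
            tree_base += leaf.value * float(np.prod(leaf.betas))
        base += tree_base
    k = len(estimators)
    return total / k, base / k


# ---------------------------------------------------------------------------
# pipeline-facing operations

def shapley_attribution(model, matrix: BinMatrix) -> AttributionResult:
    """Attribute the trained forest's RA probability over the retained bins.

    The model must have been trained on exactly the bins of ``matrix`` (in
    order); local accuracy is verified for every sample before returning.
    """
    if getattr(model, "n_features_in_", matrix.n_bins) != matrix.n_bins:
        raise ValueError("model was trained on a different number of bins")
    shap_values, base = tree_shap_values(model, matrix.values)
    predicted = model.predict_proba(matrix.values)[:, list(model.classes_).index(1)]
    recon = base + shap_values.sum(axis=1)
    if not np.allclose(recon, predicted, atol=1e-6):
        raise AssertionError("local accuracy violated: attributions do not sum to the model output")
    direction: dict[str, int] = {}
    for j, b in enumerate(matrix.bins):
        col, sv = matrix.values[:, j], shap_values[:, j]
        if np.allclose(sv, 0.0) or np.std(col) == 0 or np.std(sv) == 0:
            direction[b.bin_id] = 0
        else:
            r = np.corrcoef(col, sv)[0, 1]
            direction[b.bin_id] = int(np.sign(r)) if np.isfinite(r) else 0
    return AttributionResult(shap_values=shap_values, base_value=float(base),
                             bins=list(matrix.bins), direction=direction)


def rank_attributions(result: AttributionResult, k: int) -> list[RankedAttribution]:
    """Top-``k`` bins by mean absolute attribution (descending, ties by
    bin_id), each annotated with its direction; repeated metabolites keep
    every one of their bins."""
    if k > len(result.bins):
        raise ValueError("k exceeds the number of retained bins")
    mean_abs = result.mean_abs()
    order = sorted(range(len(result.bins)), key=lambda j: (-mean_abs[j], result.bins[j].bin_id))
    ranking = [RankedAttribution(bin=result.bins[j], mean_abs_shap=float(mean_abs[j]),
                                 direction=result.direction[result.bins[j].bin_id])
               for j in order[:k]]
    result.ranking = ranking
    return ranking


def compare_selections(plsda_result, ml_ranking: list[RankedAttribution]) -> MarkerComparison:
    """Set algebra between the PLS-DA and ML marker selections, collapsed to
    metabolite names. The ML side splits its ranked bins by attribution
    direction (+1 → RA, −1 → OA)."""
    set_plsda_oa = {r.bin.metabolite_name for r in plsda_result.ranking_OA}
    set_plsda_ra = {r.bin.metabolite_name for r in plsda_result.ranking_RA}
    set_ml_oa = {r.bin.metabolite_name for r in ml_ranking if r.direction < 0}
    set_ml_ra = {r.bin.metabolite_name for r in ml_ranking if r.direction > 0}
    return MarkerComparison(set_plsda_OA=set_plsda_oa, set_plsda_RA=set_plsda_ra,
                            set_ml_OA=set_ml_oa, set_ml_RA=set_ml_ra)


def run_report(*, normalization, stump_results, perfect_set, separation,
               best_params, metrics_rfe, metrics_all, attribution,
               ml_ranking, comparison, seeds: dict) -> dict:
    """Assemble the machine-readable run summary from completed stage
    outputs. Deterministic inputs give a byte-identical JSON serialization.
    """
    for name, value in [("normalization", normalization), ("stump_results", stump_results),
                        ("best_params", best_params), ("metrics_rfe", metrics_rfe),
                        ("attribution", attribution)]:
        if value is None:
            raise ValueError(f"missing stage output: {name}")
    return {
        "normalization": {
            "method": normalization.method,
            "silhouette": round(normalization.silhouette, 6),
            "all_silhouettes": {m: round(s, 6) for m, s in sorted((normalization.all_silhouettes or {}).items())},
            "pc_variance": [round(v, 6) for v in normalization.pc_variance],
        },
        "stump_screen": {
            "n_bins": len(stump_results),
            "perfect_bins": sorted(perfect_set),
            "separation": {
                bin_id: {
                    "centroid_distance": round(m.centroid_distance, 6),
                    "sd_OA": round(m.sd_OA, 6),
                    "sd_RA": round(m.sd_RA, 6),
                    "three_sigma_pass": m.three_sigma_pass,
                    "fdr": round(m.fdr, 6),
                } for bin_id, m in sorted(separation.items())
            },
        },
        "best_params": dict(zip(
            ("n_rfe", "n_est", "max_depth", "min_samples_split",
             "min_samples_leaf", "max_features_rule", "criterion"),
            best_params.as_tuple())),
        "loocv": {
            "with_rfe": metrics_rfe.as_dict(),
            "without_rfe": metrics_all.as_dict() if metrics_all is not None else None,
            "predictions": [int(v) for v in metrics_rfe.predictions],
            "probabilities": [round(float(v), 6) for v in metrics_rfe.probabilities],
        },
        "attribution": {
            "scale": attribution.scale,
            "base_value": round(attribution.base_value, 6),
            "top_bins": [
                {"bin_id": r.bin.bin_id, "metabolite": r.bin.metabolite_name,
                 "mean_abs_shap": round(r.mean_abs_shap, 6), "direction": r.direction}
                for r in ml_ranking
            ],
        },
        "marker_comparison": {
            "overlap_OA": sorted(comparison.overlap_OA),
            "overlap_RA": sorted(comparison.overlap_RA),
            "unique_plsda_OA": sorted(comparison.unique_plsda_OA),
            "unique_plsda_RA": sorted(comparison.unique_plsda_RA),
            "unique_ml_OA": sorted(comparison.unique_ml_OA),
            "unique_ml_RA": sorted(comparison.unique_ml_RA),
            "ambiguous": sorted(comparison.ambiguous),
        },
        "seeds": {k: int(v) for k, v in sorted(seeds.items())},
    }
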