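"""SVM-based recursive feature elimination and random-forest
leave-one-out cross-validation.

RFE fits a linear-kernel SVM on the remaining bins, ranks bins by squared
weight, and removes the single least-important bin per iteration. Because
the one-step elimination path is nested, the full elimination order is
computed once and any retained-set size is a prefix of it.

The forest is evaluated with leave-one-out cross-validation (LOOCV): each
of the n samples is predicted by a forest trained on the other n−1, and the
six reported metrics (MCC, accuracy, precision, recall, F1, ROC-AUC) are
computed once on the pooled held-out predictions, RA being the positive
class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score, roc_auc_score
from sklearn.svm import SVC

from sfmetab.core_io import BinMatrix

MAX_FEATURES_RULES = ("log2", "sqrt")   # plus any explicit positive count
CRITERIA = ("gini", "entropy", "log_loss")

#: SVM regularization used throughout RFE (the C of the linear-kernel SVM)
SVM_C = 1.0


@dataclass(frozen=True)
class HyperParams:
    """One candidate model: the RFE retained-set size plus six
    random-forest hyperparameters."""

    n_rfe: int = 50                      # bins retained by RFE
    n_est: int = 100                     # trees in the forest
    max_depth: int = 6
    min_samples_split: int = 10
    min_samples_leaf: int = 6
    max_features_rule: int | str = "log2"  # explicit count, "log2", or "sqrt"
    criterion: str = "log_loss"

    def __post_init__(self) -> None:
        for name in ("n_rfe", "n_est", "max_depth", "min_samples_split"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")
        if isinstance(self.max_features_rule, str) and self.max_features_rule not in MAX_FEATURES_RULES:
            raise ValueError(f"unknown max_features rule {self.max_features_rule!r}")
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown split criterion {self.criterion!r}")

    def resolve_max_features(self, n_features: int) -> int:
        """Number of candidate features per split, e.g. ⌊log₂(N_RFE)⌋ = 5
        when 50 bins are retained."""
        if self.max_features_rule == "log2":
            m = int(math.floor(math.log2(n_features)))
        elif self.max_features_rule == "sqrt":
            m = int(math.floor(math.sqrt(n_features)))
        else:
            m = int(self.max_features_rule)
        return max(1, min(m, n_features))

    def as_tuple(self) -> tuple:
        return (self.n_rfe, self.n_est, self.max_depth, self.min_samples_split,
                self.min_samples_leaf, self.max_features_rule, self.criterion)


@dataclass
class CVMetrics:
    mcc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_auc: float
    predictions: np.ndarray | None = field(default=None, repr=False)
    probabilities: np.ndarray | None = field(default=None, repr=False)

    def as_dict(self) -> dict[str, float]:
        return {k: round(float(getattr(self, k)), 6)
                for k in ("mcc", "accuracy", "precision", "recall", "f1", "roc_auc")}


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient from a confusion matrix, with the
    0/0 → 0 convention."""
    if min(tp, tn, fp, fn) < 0 or tp + tn + fp + fn < 1:
        raise ValueError("confusion counts must be nonnegative with total >= 1")
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(den)


def rfe_ranking(matrix: BinMatrix, svm_c: float = SVM_C) -> list[str]:
    """Full SVM-RFE elimination order: bin ids from most to least important.

    A linear-kernel SVM is refitted after every single-bin removal; the bin
    with the smallest squared weight is eliminated. Deterministic for a
    fixed matrix and regularization.
    """
    selector = RFE(estimator=SVC(kernel="linear", C=svm_c),
                   n_features_to_select=1, step=1)
    selector.fit(matrix.values, matrix.y)
    order = np.argsort(selector.ranking_, kind="stable")
    return [matrix.bins[j].bin_id for j in order]


def rfe_select(matrix: BinMatrix, n_keep: int,
               ranking: list[str] | None = None) -> list[str]:
    """Bin ids retained by SVM-RFE at retained-set size ``n_keep``
    (equivalently, the ``n_keep`` most important bins of the full
    elimination order), returned in matrix column order."""
    if not 1 <= n_keep <= matrix.n_bins:
        raise ValueError("n_keep must be in [1, n_bins]")
    if ranking is None:
        ranking = rfe_ranking(matrix)
    keep = set(ranking[:n_keep])
    return [b.bin_id for b in matrix.bins if b.bin_id in keep]


def build_forest(params: HyperParams, n_features: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=params.n_est,
        max_depth=params.max_depth,
        min_samples_split=params.min_samples_split,
        min_samples_leaf=params.min_samples_leaf,
        max_features=params.resolve_max_features(n_features),
        criterion=params.criterion,
        random_state=seed,
        n_jobs=1,
    )


def fit_final_forest(matrix: BinMatrix, params: HyperParams, seed: int) -> RandomForestClassifier:
    """Forest with the given hyperparameters trained on every sample
    (used for post-hoc attribution)."""
    forest = build_forest(params, matrix.n_bins, seed)
    forest.fit(matrix.values, matrix.y)
    return forest


def rf_loocv(matrix: BinMatrix, params: HyperParams, seed: int = 0) -> CVMetrics:
    """Leave-one-out evaluation of a random forest with the given
    hyperparameters.

    Exactly ``n_samples`` folds; per-fold seeds are derived deterministically
    from the master seed, so a fixed (matrix, params, seed) triple yields
    identical metrics. Metrics are computed on the pooled held-out class
    predictions; ROC-AUC uses the pooled held-out RA probabilities.
    """
    y = matrix.y
    n = matrix.n_samples
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    fold_seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    preds = np.empty(n, dtype=int)
    probs = np.empty(n, dtype=float)
    for i in range(n):
        train = np.arange(n) != i
        y_train = y[train]
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"training fold {i} lost a class entirely")
        forest = build_forest(params, matrix.n_bins, int(fold_seeds[i]))
        forest.fit(matrix.values[train], y_train)
        proba = forest.predict_proba(matrix.values[i:i + 1])[0]
        # argmax over class order == forest.predict, without re-validation
        preds[i] = int(forest.classes_[int(np.argmax(proba))])
        probs[i] = float(proba[list(forest.classes_).index(1)])
    tp = int(np.sum((preds == 1) & (y == 1)))
    tn = int(np.sum((preds == 0) & (y == 0)))
    fp = int(np.sum((preds == 1) & (y == 0)))
    fn = int(np.sum((preds == 0) & (y == 1)))
    return CVMetrics(
        mcc=mcc(tp, tn, fp, fn),
        accuracy=float(accuracy_score(y, preds)),
        precision=float(precision_score(y, preds, pos_label=1, zero_division=0)),
        recall=float(recall_score(y, preds, pos_label=1, zero_division=0)),
        f1=float(f1_score(y, preds, pos_label=1, zero_division=0)),
        roc_auc=float(roc_auc_score(y, probs)),
        predictions=preds,
        probabilities=probs,
    )
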