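"""Normalization methods, principal-component exploration, and
silhouette-guided scaler selection.

Five column-wise scalers are considered: Z-score, min–max, max-absolute,
robust (median/IQR), and combined median + Pareto (median centering followed
by division by the square root of the standard deviation). The scaler that
maximizes the label-based silhouette score — how cleanly the OA and RA
groups separate in the scaled bin space — wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from sfmetab.core_io import BinMatrix

logger = logging.getLogger(__name__)

#: candidate methods in evaluation (and tie-break) order
METHODS = ("zscore", "minmax", "maxabs", "robust", "median_pareto")


@dataclass
class NormalizationReport:
    method: str
    scaled: BinMatrix
    silhouette: float
    pc_variance: list[float]
    all_silhouettes: dict[str, float] | None = None


def _column_transform(values: np.ndarray, method: str) -> np.ndarray:
    """Apply one scaler column-wise; raises naming the offending column when
    a spread denominator is zero."""
    x = np.asarray(values, dtype=float)

    def _check_spread(spread: np.ndarray, what: str) -> None:
        bad = np.flatnonzero(spread == 0)
        if bad.size:
            raise ZeroDivisionError(f"{method}: zero {what} in column index {int(bad[0])}")

    if method == "zscore":
        sd = x.std(axis=0, ddof=1)
        _check_spread(sd, "standard deviation")
        return (x - x.mean(axis=0)) / sd
    if method == "minmax":
        lo, hi = x.min(axis=0), x.max(axis=0)
        _check_spread(hi - lo, "range")
        return (x - lo) / (hi - lo)
    if method == "maxabs":
        m = np.abs(x).max(axis=0)
        _check_spread(m, "max absolute value")
        return x / m
    if method == "robust":
        med = np.median(x, axis=0)
        iqr = np.percentile(x, 75, axis=0) - np.percentile(x, 25, axis=0)
        _check_spread(iqr, "interquartile range")
        return (x - med) / iqr
    if method == "median_pareto":
        sd = x.std(axis=0, ddof=1)
        _check_spread(sd, "standard deviation")
        return (x - np.median(x, axis=0)) / np.sqrt(sd)
    raise ValueError(f"unknown normalization method {method!r}")


def normalize(matrix: BinMatrix, method: str) -> BinMatrix:
    """Return a new matrix with each bin column rescaled by ``method``."""
    return BinMatrix(values=_column_transform(matrix.values, method),
                     sample_ids=list(matrix.sample_ids),
                     labels=list(matrix.labels), bins=list(matrix.bins))


def pca(matrix: BinMatrix, n_components: int) -> tuple[np.ndarray, list[float]]:
    """Principal components of the (already scaled) matrix.

    Columns are mean-centered before decomposition but not re-scaled — the
    scaling choice was made upstream. Returns (scores, per-component
    fraction of total variance).
    """
    limit = min(matrix.n_samples - 1, matrix.n_bins)
    if not 1 <= n_components <= limit:
        raise ValueError(f"n_components must be in [1, {limit}]")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(matrix.values)
    return scores, [float(v) for v in model.explained_variance_ratio_]


def silhouette_by_label(matrix: BinMatrix, use_labels: bool = True) -> float:
    """Mean silhouette over samples, Euclidean distance in the full scaled
    bin space, with the OA/RA diagnosis labels as the cluster assignment.

    ``use_labels=False`` instead scores an unsupervised 2-means clustering
    of the same space (exposed for sensitivity analysis).
    """
    summary = matrix.class_summary()
    if min(summary.n_OA, summary.n_RA) < 2:
        raise ValueError("silhouette needs at least 2 samples per class")
    if use_labels:
        assignment = matrix.y
    else:
        from sklearn.cluster import KMeans
        assignment = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(matrix.values)
    return float(silhouette_score(matrix.values, assignment, metric="euclidean"))


def select_normalization(matrix: BinMatrix, n_pca_components: int = 3,
                         use_labels: bool = True) -> NormalizationReport:
    """Evaluate every candidate scaler and return the report of the
    silhouette-maximizing one; ties go to the earlier method in
    :data:`METHODS`. Methods whose preconditions fail (zero-spread columns)
    are skipped with a logged warning.
    """
    silhouettes: dict[str, float] = {}
    scaled_by_method: dict[str, BinMatrix] = {}
    for method in METHODS:
        try:
            scaled = normalize(matrix, method)
            silhouettes[method] = silhouette_by_label(scaled, use_labels=use_labels)
            scaled_by_method[method] = scaled
        except (ZeroDivisionError, ValueError) as exc:
            logger.warning("normalization %s skipped: %s", method, exc)
    if not silhouettes:
        raise ValueError("every normalization method failed its preconditions")
    best = max(silhouettes, key=lambda m: (silhouettes[m], -METHODS.index(m)))
    scaled = scaled_by_method[best]
    n_comp = min(n_pca_components, scaled.n_samples - 1, scaled.n_bins)
    _, pc_variance = pca(scaled, n_comp)
    return NormalizationReport(method=best, scaled=scaled,
                               silhouette=silhouettes[best],
                               pc_variance=pc_variance,
                               all_silhouettes=silhouettes)
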