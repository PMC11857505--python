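"""Partial least squares discriminant analysis (PLS-DA) and coefficient-based
metabolite-bin ranking.

The class code (OA=0, RA=1) is regressed on the scaled bin matrix with a
deflation-based (NIPALS) PLS fit. Each bin receives one signed regression
coefficient: negative ⇔ elevated intensity pushes the prediction toward OA,
positive ⇔ toward RA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from sfmetab.core_io import BinInfo, BinMatrix


@dataclass
class RankedBin:
    bin: BinInfo
    coefficient: float


@dataclass
class PlsdaResult:
    n_components: int
    scores: np.ndarray                  # n_samples × n_components latent scores
    coefficients: np.ndarray            # signed, one per bin
    x_weights: np.ndarray               # successive weight vectors (columns)
    bins: list[BinInfo]
    ranking_OA: list[RankedBin] = field(default_factory=list)
    ranking_RA: list[RankedBin] = field(default_factory=list)
    degenerate: bool = False            # all-zero or tied coefficients


def fit_plsda(matrix: BinMatrix, n_components: int = 2) -> PlsdaResult:
    """Fit PLS-DA on a scaled bin matrix against the 0/1 class code.

    Deterministic for a fixed input. With one component, the coefficient
    vector is proportional to the per-bin covariance with the centered
    response.
    """
    if n_components > matrix.n_samples - 1:
        raise ValueError("n_components must not exceed n_samples - 1")
    y = matrix.y.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("PLS-DA needs both classes present")
    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(matrix.values, y)
    return PlsdaResult(n_components=n_components,
                       scores=model.x_scores_,
                       coefficients=np.asarray(model.coef_).ravel(),
                       x_weights=model.x_weights_,
                       bins=list(matrix.bins))


def rank_bins(result: PlsdaResult, k: int = 10) -> PlsdaResult:
    """Attach the per-class top-``k`` rankings to ``result``.

    ``ranking_OA`` holds the ``k`` most-negative-coefficient bins (ascending),
    ``ranking_RA`` the ``k`` most-positive (descending). Ties are broken by
    bin_id lexical order and flagged via ``result.degenerate``. With
    ``k ≤ n_bins/2`` the two lists are disjoint by construction.
    """
    n = len(result.bins)
    if k > n // 2:
        raise ValueError("k must not exceed n_bins/2")
    coef = result.coefficients
    order = sorted(range(n), key=lambda j: (coef[j], result.bins[j].bin_id))
    result.ranking_OA = [RankedBin(result.bins[j], float(coef[j])) for j in order[:k]]
    result.ranking_RA = [RankedBin(result.bins[j], float(coef[j])) for j in order[-k:][::-1]]
    result.degenerate = len(np.unique(coef)) < n or not np.any(coef)
    return result


def ranking_metabolites(ranking: list[RankedBin]) -> set[str]:
    """Collapse a ranked bin list to its metabolite-name set."""
    return {r.bin.metabolite_name for r in ranking}
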