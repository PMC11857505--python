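"""Per-bin decision-stump screening and univariate separation metrics.

A decision stump is a single-split, single-feature classifier. Each
metabolite bin is swept over every candidate threshold (midpoints of
consecutive sorted unique values, plus the two trivial all-one-class cuts)
and both polarities, and scored with the Matthews correlation coefficient
(MCC). Bins whose best stump reaches MCC = 1.0 separate the classes
perfectly and are set aside; the rest feed the multivariate RFE + forest
stage.

Separation quality of a bin is quantified by the distance between class
centroids, the per-class standard deviations with a three-sigma verdict,
and the Fisher discriminant ratio d² / (sd_OA² + sd_RA²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sfmetab.core_io import CLASS_CODE, BinInfo, BinMatrix

HIGH_RA = "high->RA"
HIGH_OA = "high->OA"


@dataclass
class StumpResult:
    threshold: float
    polarity: str               # HIGH_RA: values above threshold predict RA
    mcc: float
    margin: float = 0.0         # distance from threshold to nearest sample
    bin: BinInfo | None = None


@dataclass
class SeparationMetrics:
    centroid_distance: float
    sd_OA: float
    sd_RA: float
    three_sigma_pass: bool
    fdr: float


def _as_codes(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return np.array([CLASS_CODE[str(l)] for l in arr], dtype=int)
    return arr.astype(int)


def _mcc_from_counts(tp, tn, fp, fn):
    """Vectorized MCC with the 0/0 → 0 convention."""
    tp = np.asarray(tp, dtype=float)
    num = tp * tn - np.asarray(fp, float) * fn
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.sqrt(np.where(den > 0, den, 1.0)), 0.0)
    return out


def stump_mcc(values, labels, bin_info: BinInfo | None = None) -> StumpResult:
    """Best single-threshold split of one bin, maximizing MCC over every
    candidate threshold and both polarities.

    Candidate thresholds are the midpoints of consecutive sorted unique
    values; the two degenerate cuts (everything on one side) score MCC 0 by
    the zero-denominator convention. Among equal-MCC candidates the
    threshold with the largest margin (half the gap between the flanking
    values) wins; a polarity tie resolves to high→RA.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    y = _as_codes(labels)
    n = v.size
    n_ra = int(y.sum())
    n_oa = n - n_ra
    if n_oa == 0 or n_ra == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(v, kind="stable")
    vs, ys = v[order], y[order]
    cuts = np.flatnonzero(np.diff(vs) > 0)          # cut after sorted index i
    if cuts.size == 0:
        return StumpResult(threshold=float(vs[0]), polarity=HIGH_RA, mcc=0.0,
                           margin=0.0, bin=bin_info)

    cum_ra = np.cumsum(ys)
    ra_low = cum_ra[cuts]
    low_n = cuts + 1
    oa_low = low_n - ra_low
    # polarity high->RA: the high side predicts RA
    tp, fp = n_ra - ra_low, n_oa - oa_low
    fn, tn = ra_low, oa_low
    mcc_ra = _mcc_from_counts(tp, tn, fp, fn)

    margins = (vs[cuts + 1] - vs[cuts]) / 2.0
    best = np.maximum(mcc_ra, -mcc_ra)
    top = best.max()
    # largest-margin tie-break among maximizers
    contenders = np.flatnonzero(best >= top - 1e-12)
    pick = contenders[np.argmax(margins[contenders])]
    polarity = HIGH_RA if mcc_ra[pick] >= -mcc_ra[pick] else HIGH_OA
    threshold = float((vs[cuts[pick]] + vs[cuts[pick] + 1]) / 2.0)
    return StumpResult(threshold=threshold, polarity=polarity, mcc=float(best[pick]),
                       margin=float(margins[pick]), bin=bin_info)


def screen_bins(matrix: BinMatrix, perfect_tol: float = 1e-9) -> tuple[list[StumpResult], set[str]]:
    """Stump-screen every bin of a cleaned, scaled matrix.

    Returns the per-bin results ranked by MCC (descending, ties by bin_id)
    and the *perfect set* — bin ids whose stump reaches MCC 1.0. Downstream
    multivariate modelling operates on the complement of the perfect set.
    """
    results = [stump_mcc(matrix.values[:, j], matrix.y, bin_info=matrix.bins[j])
               for j in range(matrix.n_bins)]
    results.sort(key=lambda r: (-r.mcc, r.bin.bin_id))
    perfect = {r.bin.bin_id for r in results if r.mcc >= 1.0 - perfect_tol}
    return results, perfect


def separation_metrics(values, labels) -> SeparationMetrics:
    """Centroid distance, per-class SDs (n−1 denominator), three-sigma
    verdict, and Fisher discriminant ratio for one bin.

    ``fdr = d² / (sd_OA² + sd_RA²)`` (0 when the denominator vanishes);
    the three-sigma rule passes iff 3·sd_OA < d and 3·sd_RA < d.
    """
    v = np.asarray(values, dtype=float)
    y = _as_codes(labels)
    oa, ra = v[y == 0], v[y == 1]
    if oa.size < 2 or ra.size < 2:
        raise ValueError("separation metrics need at least 2 samples per class")
    d = float(abs(oa.mean() - ra.mean()))
    sd_oa = float(oa.std(ddof=1))
    sd_ra = float(ra.std(ddof=1))
    denom = sd_oa ** 2 + sd_ra ** 2
    fdr = d ** 2 / denom if denom > 0 else 0.0
    return SeparationMetrics(centroid_distance=d, sd_OA=sd_oa, sd_RA=sd_ra,
                             three_sigma_pass=(3 * sd_oa < d) and (3 * sd_ra < d),
                             fdr=fdr)


def fisher_discriminant_ratio(d: float, sd_a: float, sd_b: float) -> float:
    """Fisher discriminant ratio from summary statistics: squared centroid
    distance over the summed per-class variances."""
    denom = sd_a ** 2 + sd_b ** 2
    return d ** 2 / denom if denom > 0 else 0.0


def three_sigma_verdict(d: float, sd_a: float, sd_b: float) -> bool:
    """Three-sigma separation rule from summary statistics."""
    return (3 * sd_a < d) and (3 * sd_b < d)
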