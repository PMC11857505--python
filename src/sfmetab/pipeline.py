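"""End-to-end orchestration: normalization selection → stump screen →
GA-tuned RFE + random-forest LOOCV → Shapley attribution → marker
comparison → run summary."""

from __future__ import annotations

from dataclasses import dataclass

from sfmetab import attribution as attr
from sfmetab import ga as ga_mod
from sfmetab import model_select, plsda, preprocessing, stump
from sfmetab.core_io import BinMatrix


@dataclass
class PipelineResult:
    summary: dict
    normalization: preprocessing.NormalizationReport
    perfect_set: set[str]
    ga_result: ga_mod.GAResult
    metrics_rfe: model_select.CVMetrics
    metrics_all: model_select.CVMetrics
    attribution: attr.AttributionResult


def run_pipeline(matrix: BinMatrix, seed: int = 0,
                 space: ga_mod.SearchSpace | None = None,
                 ga_config: ga_mod.GAConfig | None = None,
                 normalization_method: str = "auto",
                 plsda_components: int = 2, top_k: int = 20,
                 plsda_top: int = 10) -> PipelineResult:
    """Run the whole workflow on a labelled bin matrix.

    ``normalization_method="auto"`` picks the silhouette-maximizing scaler;
    the GA tunes the RFE size and forest hyperparameters on the non-perfect
    bins; the tuned model is refitted on all samples for attribution.
    """
    if normalization_method == "auto":
        report = preprocessing.select_normalization(matrix)
    else:
        scaled = preprocessing.normalize(matrix, normalization_method)
        report = preprocessing.NormalizationReport(
            method=normalization_method, scaled=scaled,
            silhouette=preprocessing.silhouette_by_label(scaled),
            pc_variance=preprocessing.pca(scaled, min(3, scaled.n_samples - 1, scaled.n_bins))[1],
            all_silhouettes=None)
    scaled = report.scaled

    stump_results, perfect = stump.screen_bins(scaled)
    separation = {r.bin.bin_id: stump.separation_metrics(
        scaled.values[:, scaled.bin_ids.index(r.bin.bin_id)], scaled.y)
        for r in stump_results if r.bin.bin_id in perfect}

    plsda_result = plsda.rank_bins(
        plsda.fit_plsda(scaled, n_components=plsda_components), k=plsda_top)

    nonperfect = scaled.drop_bins(perfect)
    ga_config = ga_config or ga_mod.GAConfig(seed=seed)
    ga_result = ga_mod.run_ga(nonperfect, space=space, config=ga_config)
    best = ga_result.best

    ranking = model_select.rfe_ranking(nonperfect)
    retained = model_select.rfe_select(nonperfect, min(best.n_rfe, nonperfect.n_bins),
                                       ranking=ranking)
    retained_matrix = nonperfect.select_bins(retained)
    metrics_rfe = model_select.rf_loocv(retained_matrix, best, seed=seed)
    metrics_all = model_select.rf_loocv(nonperfect, best, seed=seed)

    forest = model_select.fit_final_forest(retained_matrix, best, seed=seed)
    attribution = attr.shapley_attribution(forest, retained_matrix)
    ml_ranking = attr.rank_attributions(attribution, min(top_k, retained_matrix.n_bins))
    comparison = attr.compare_selections(plsda_result, ml_ranking)

    summary = attr.run_report(
        normalization=report, stump_results=stump_results, perfect_set=perfect,
        separation=separation, best_params=best, metrics_rfe=metrics_rfe,
        metrics_all=metrics_all, attribution=attribution, ml_ranking=ml_ranking,
        comparison=comparison, seeds={"pipeline": seed, "ga": ga_config.seed})
    return PipelineResult(summary=summary, normalization=report, perfect_set=perfect,
                          ga_result=ga_result, metrics_rfe=metrics_rfe,
                          metrics_all=metrics_all, attribution=attribution)
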