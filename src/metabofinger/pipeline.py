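"""End-to-end orchestration: pretreat, select, and cross-validate batches."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import FeatureTable, RunConfig
from .multivariate import ModelEvaluation, evaluate_models, multivariate_select
from .preprocess import PretreatmentResult, run_pretreatment
from .simulate import SyntheticTruth
from .univariate import univariate_select
from .validate import (
    match_features,
    selection_metrics,
    selection_records,
    validate_selection,
)


@dataclass
class BatchAnalysis:
    """One batch taken through pretreatment and both selection arms."""

    pretreatment: PretreatmentResult
    univariate: pd.DataFrame
    evaluation: ModelEvaluation
    records: pd.DataFrame  # per-feature selection records

    @property
    def selected_ids(self) -> list:
        return list(self.records.index[self.records["combined_selected"]])


def analyze_batch(table: FeatureTable, config: RunConfig | None = None) -> BatchAnalysis:
    """Pretreat one run and apply the univariate and multivariate arms."""
    cfg = config or RunConfig()
    pre = run_pretreatment(table, cfg)
    uni = univariate_select(pre.univariate_snapshot, cfg)
    bio_cols = pre.table.columns_of("biological")
    X = pre.table.intensities[bio_cols].T
    y = pre.table.samples.loc[bio_cols, "group"].to_numpy()
    evaluation, model = evaluate_models(X, y, cfg)
    multi = multivariate_select(model, evaluation.mda, cfg)
    records = selection_records(uni, multi, pre.table.feature_ids)
    return BatchAnalysis(pre, uni, evaluation, records)


@dataclass
class CrossBatchResult:
    """Validated selection across two independent batches."""

    batch1: BatchAnalysis
    batch2: BatchAnalysis
    matches: pd.DataFrame
    validated: pd.DataFrame

    @property
    def validated_ids(self) -> list:
        hits = self.validated[self.validated["validated"]]
        return list(hits["feature_id_1"])

    def metrics(self, truth: SyntheticTruth) -> dict:
        """Sensitivity/FDR of the validated set and of each single batch."""
        return {
            "validated": selection_metrics(self.validated_ids, truth).to_dict(),
            "batch1": selection_metrics(self.batch1.selected_ids, truth).to_dict(),
            "batch2": selection_metrics(self.batch2.selected_ids, truth).to_dict(),
        }


def analyze_experiment(
    table1: FeatureTable, table2: FeatureTable, config: RunConfig | None = None
) -> CrossBatchResult:
    """Analyze two replicate batches and keep only cross-confirmed features."""
    cfg = config or RunConfig()
    b1 = analyze_batch(table1, cfg)
    b2 = analyze_batch(table2, cfg)
    matches = match_features(
        b1.pretreatment.univariate_snapshot,
        b2.pretreatment.univariate_snapshot,
        mz_ppm=cfg.match_mz_ppm,
        config=cfg,
    )
    validated = validate_selection(b1.records, b2.records, matches, cfg)
    return CrossBatchResult(b1, b2, matches, validated)
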