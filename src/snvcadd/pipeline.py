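"""End-to-end composition: annotate -> expand -> scale -> split -> tune ->
train -> evaluate, wired for the synthetic fixture bundle or for externally
loaded resources."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import VariantAnnotator
from .features import FeatureExpander, FeatureSpec, SdScaler, default_feature_spec
from .model import (
    EvaluationMetrics,
    ModelConfig,
    TrainedModel,
    evaluate,
    split_train_test,
    train_logistic,
    tune_l2,
)
from .synth import FixtureBundle


def build_annotator(bundle: FixtureBundle) -> VariantAnnotator:
    return VariantAnnotator(
        genome=bundle.genome,
        genes=bundle.genes,
        per_base_tracks=bundle.per_base_tracks,
        interval_tracks=bundle.interval_tracks,
        remap=bundle.remap,
    )


@dataclass
class FitResult:
    model: TrainedModel
    scaler: SdScaler
    metrics: EvaluationMetrics
    selected_l2: float
    tuning_mean_accuracy: dict[float, float] | None
    train_index: np.ndarray
    test_index: np.ndarray
    matrix: pd.DataFrame
    labels: np.ndarray


def fit_impact_model(
    labeled: pd.DataFrame,
    annotator: VariantAnnotator,
    spec: FeatureSpec | None = None,
    config: ModelConfig | None = None,
    tune: bool = False,
    l2: float = 1.0,
) -> FitResult:
    """Train and evaluate an impact model on a labeled variant set.

    The labeled rows are split 90/10; the scaler is fitted on the training
    rows only; L2 is either tuned by repeated sub-sampling on the training
    rows or fixed at ``l2``.
    """
    spec = spec or default_feature_spec()
    config = config or ModelConfig()
    annotated = annotator.annotate(labeled[["chrom", "pos", "ref", "alt"]])
    matrix = FeatureExpander(spec).fit(annotated).transform(annotated)
    labels = labeled["label"].to_numpy(dtype=float)
    train_idx, test_idx = split_train_test(
        len(labels), config.train_fraction, config.seed
    )
    scaler = SdScaler().fit(matrix.iloc[train_idx])
    x_train = scaler.transform(matrix.iloc[train_idx])
    x_test = scaler.transform(matrix.iloc[test_idx])
    tuning_means = None
    if tune:
        l2, tuning_means, _ = tune_l2(x_train, labels[train_idx], config)
    model = train_logistic(
        x_train,
        labels[train_idx],
        l2=l2,
        max_iter=config.max_iterations,
        scaling=scaler.params(),
        spec_checksum=spec.checksum(),
        seed=config.seed,
    )
    metrics = evaluate(model, x_test, labels[test_idx])
    return FitResult(
        model=model,
        scaler=scaler,
        metrics=metrics,
        selected_l2=l2,
        tuning_mean_accuracy=tuning_means,
        train_index=train_idx,
        test_index=test_idx,
        matrix=matrix,
        labels=labels,
    )
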