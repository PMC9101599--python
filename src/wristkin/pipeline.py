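"""End-to-end experiment driver: simulate -> extract -> split -> train -> evaluate."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .curves import default_curves
from .evaluate import (
    DEFAULT_TOLERANCE,
    EvaluationReport,
    evaluate_model,
    feature_score_correlation_matrix,
)
from .features import ExtractionParams, build_feature_table
from .models import ALGORITHMS, ModelSpec, TrainedModel, train_model
from .preprocess import LabeledDataset, split_dataset, zscore_apply, zscore_fit
from .simulate import make_cohort


@dataclass
class ExperimentResult:
    """Everything the standard experiment produces."""

    features: LabeledDataset
    train: LabeledDataset
    test: LabeledDataset
    models: dict[str, TrainedModel]
    reports: dict[str, EvaluationReport]
    correlation_matrix: pd.DataFrame = field(repr=False)


def run_experiment(
    n_patients: int = 25,
    n_controls: int = 10,
    seed: int = 0,
    score_sampler=None,
    train_frac: float = 0.7,
    split_level: str = "sample",
    tolerance: float = DEFAULT_TOLERANCE,
    fit_stats_on: str = "train",
    algorithms: tuple = ALGORITHMS,
    extraction: ExtractionParams | None = None,
    sample_rate: float | None = None,
) -> ExperimentResult:
    """Run the full pipeline on a synthetic cohort.

    Simulates the cohort, extracts the seven features per trial, splits
    70/30, standardizes (statistics fitted on the training split by
    default; ``fit_stats_on="all"`` fits on the whole dataset first),
    trains the requested models and evaluates each on the test split.
    """
    sim_kwargs = {} if sample_rate is None else {"sample_rate": sample_rate}
    curves = default_curves()
    cohort = make_cohort(
        n_patients, n_controls, score_sampler=score_sampler, seed=seed,
        curves=curves, **sim_kwargs,
    )
    table = build_feature_table(cohort, curves, extraction)
    dataset = LabeledDataset(table)
    corr = feature_score_correlation_matrix(dataset)

    train_raw, test_raw = split_dataset(dataset, train_frac, seed=seed, level=split_level)
    stats = zscore_fit(dataset if fit_stats_on == "all" else train_raw)
    train = zscore_apply(train_raw, stats)
    test = zscore_apply(test_raw, stats)

    models: dict[str, TrainedModel] = {}
    reports: dict[str, EvaluationReport] = {}
    for algo in algorithms:
        model = train_model(ModelSpec(algorithm=algo, seed=seed), train)
        models[algo] = model
        reports[algo] = evaluate_model(model, test, tol=tolerance)
    return ExperimentResult(
        features=dataset,
        train=train,
        test=test,
        models=models,
        reports=reports,
        correlation_matrix=corr,
    )
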