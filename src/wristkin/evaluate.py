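"""Model-evaluation indices and correlation validation.

A prediction counts as correct when it falls within a clinical tolerance
of the clinician's score (3 scale points by default, boundary inclusive):

    accuracy = 100 * Ns / Nt

with Ns the number of test samples within tolerance and Nt the test-set
size.  Alongside accuracy the report carries MAE, MSE, the coefficient of
determination R^2 = 1 - sum(y - yhat)^2 / sum(y - ybar)^2, and the Pearson
and Spearman correlations (with two-sided p-values) between predicted and
clinician scores.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ContractViolationError, UndefinedCorrelationError
from .features import FEATURE_NAMES
from .models import TrainedModel
from .preprocess import LabeledDataset

#: Clinical tolerance (scale points) within which a prediction is "correct".
DEFAULT_TOLERANCE = 3.0


@dataclass(frozen=True)
class EvaluationReport:
    """All evaluation indices for one trained model on one test set."""

    algorithm: str
    seed: int
    tolerance: float
    accuracy_pct: float
    mae: float
    mse: float
    r2: float
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n_test: int
    n_within: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _paired(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ContractViolationError("y_true and y_pred must be equal-length 1-D")
    if len(y_true) == 0:
        raise ContractViolationError("empty score vectors")
    return y_true, y_pred


def accuracy_within_tolerance(y_true, y_pred, tol: float = DEFAULT_TOLERANCE) -> float:
    """Percentage of samples with |y - yhat| <= tol (boundary inclusive)."""
    y_true, y_pred = _paired(y_true, y_pred)
    if tol < 0:
        raise ContractViolationError("tolerance must be non-negative")
    n_within = int(np.sum(np.abs(y_true - y_pred) <= tol))
    return 100.0 * n_within / len(y_true)


def mean_absolute_error(y_true, y_pred) -> float:
    """MAE = (1/n) sum |y_i - yhat_i|, in scale points."""
    y_true, y_pred = _paired(y_true, y_pred)
    return float(np.mean(np.abs(y_true - y_pred)))


def mean_squared_error(y_true, y_pred) -> float:
    """MSE = (1/n) sum (y_i - yhat_i)^2, in squared scale points."""
    y_true, y_pred = _paired(y_true, y_pred)
    return float(np.mean((y_true - y_pred) ** 2))


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination; may be negative for poor predictors."""
    y_true, y_pred = _paired(y_true, y_pred)
    if len(y_true) < 2:
        raise ContractViolationError("R^2 needs at least 2 samples")
    ss_tot = float(np.sum((y_true - np.mean(y_true)) ** 2))
    if ss_tot <= 0:
        raise UndefinedCorrelationError("R^2 undefined for constant y_true")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def correlations(y_true, y_pred):
    """Pearson r and Spearman rho (average ranks) with two-sided p-values.

    Returns ``(pearson_r, spearman_rho, (pearson_p, spearman_p))``.
    """
    y_true, y_pred = _paired(y_true, y_pred)
    if len(y_true) < 3:
        raise ContractViolationError("correlations need at least 3 samples")
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    pr = sps.pearsonr(y_true, y_pred)
    sr = sps.spearmanr(y_true, y_pred)
    return float(pr.statistic), float(sr.statistic), (float(pr.pvalue), float(sr.pvalue))


def feature_score_correlation_matrix(dataset: LabeledDataset) -> pd.DataFrame:
    """8x8 Pearson correlation matrix over the 7 features plus the score."""
    cols = [*FEATURE_NAMES, "score"]
    frame = dataset.frame[cols].astype(float)
    if len(frame) < 3:
        raise ContractViolationError("correlation matrix needs at least 3 samples")
    for col in cols:
        if np.ptp(frame[col].to_numpy()) == 0:
            raise UndefinedCorrelationError(f"column {col!r} is constant")
    return frame.corr(method="pearson")


def evaluate_model(
    model: TrainedModel, test: LabeledDataset, tol: float = DEFAULT_TOLERANCE
) -> EvaluationReport:
    """Predict on a standardized test set and assemble the full report."""
    y_true = test.y.astype(float)
    y_pred = model.predict_dataset(test)
    pear, spear, (pp, sp) = correlations(y_true, y_pred)
    acc = accuracy_within_tolerance(y_true, y_pred, tol)
    return EvaluationReport(
        algorithm=model.spec.algorithm,
        seed=model.spec.seed,
        tolerance=float(tol),
        accuracy_pct=acc,
        mae=mean_absolute_error(y_true, y_pred),
        mse=mean_squared_error(y_true, y_pred),
        r2=r_squared(y_true, y_pred),
        pearson_r=pear,
        pearson_p=pp,
        spearman_rho=spear,
        spearman_p=sp,
        n_test=len(y_true),
        n_within=int(round(acc * len(y_true) / 100.0)),
    )
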