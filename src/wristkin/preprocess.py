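"""Feature normalization, labeled datasets, and the train/test split.

Features are standardized to zero mean and unit (population) standard
deviation, x_i = (x - mean) / sigma(x), per feature.  Statistics are by
default fitted on the training split only and applied to both splits, which
avoids train-to-test leakage; fitting on the whole dataset before splitting
is available for compatibility with pipelines that normalize first.

The split is random at the sample (trial) level by default — a 70/30 split
of 405 trials gives 283 training and 122 test trials — with a subject-level
option that keeps all of a subject's trials on one side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateFeatureError,
    InsufficientDataError,
    InvalidParameterError,
)
from .features import FEATURE_NAMES
from .simulate import SCORE_MAX

#: Metadata columns carried alongside features when present.
METADATA_COLUMNS = ("subject_id", "hand", "shape_id", "force_n")


@dataclass
class LabeledDataset:
    """Feature vectors with clinician scores and optional normalization state.

    Wraps a DataFrame with the seven feature columns, an integer ``score``
    column (0-28), and any metadata columns.  ``norm_stats`` is ``None``
    for raw features, or the ``{feature: {"mean": m, "std": s}}`` mapping
    that produced the current (standardized) values.
    """

    frame: pd.DataFrame
    norm_stats: dict | None = field(default=None)

    def __post_init__(self) -> None:
        missing = [c for c in (*FEATURE_NAMES, "score") if c not in self.frame.columns]
        if missing:
            raise InvalidParameterError(f"dataset is missing columns: {missing}")
        X = self.frame[list(FEATURE_NAMES)].to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise InvalidParameterError("feature values must all be finite")
        y = self.frame["score"].to_numpy()
        if len(y) and (
            np.any(y < 0) or np.any(y > SCORE_MAX) or np.any(y != np.round(y))
        ):
            raise InvalidParameterError(
                f"scores must be integers in [0, {SCORE_MAX}]"
            )

    # -- basic access ------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        """``(n, 7)`` feature matrix in canonical feature order."""
        return self.frame[list(FEATURE_NAMES)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Integer score labels."""
        return self.frame["score"].to_numpy(dtype=int)

    @property
    def is_standardized(self) -> bool:
        return self.norm_stats is not None

    # -- IO ----------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, norm_stats: dict | None = None) -> "LabeledDataset":
        return cls(pd.read_csv(path), norm_stats=norm_stats)


def zscore_fit(dataset: LabeledDataset) -> dict:
    """Fit per-feature mean and population standard deviation.

    Returns ``{feature: {"mean": m, "std": s}}``.  A zero-variance feature
    cannot be standardized and raises :class:`DegenerateFeatureError`.
    """
    if dataset.n < 2:
        raise InsufficientDataError("need at least 2 samples to fit statistics")
    stats: dict = {}
    for name in FEATURE_NAMES:
        col = dataset.frame[name].to_numpy(dtype=float)
        mean = float(np.mean(col))
        std = float(np.std(col))  # population (ddof=0)
        if std <= 1e-12:
            raise DegenerateFeatureError(f"feature {name!r} has zero variance")
        stats[name] = {"mean": mean, "std": std}
    return stats


def zscore_apply(dataset: LabeledDataset, stats: dict) -> LabeledDataset:
    """Standardize features with previously fitted statistics.

    Labels and metadata are unchanged; the returned dataset carries
    ``stats`` as its normalization state.
    """
    missing = [name for name in FEATURE_NAMES if name not in stats]
    if missing:
        raise ConfigurationError(f"normalization stats missing features: {missing}")
    frame = dataset.frame.copy()
    for name in FEATURE_NAMES:
        s = stats[name]
        frame[name] = (frame[name].astype(float) - s["mean"]) / s["std"]
    return LabeledDataset(frame, norm_stats=stats)


def zscore_invert(dataset: LabeledDataset, stats: dict | None = None) -> LabeledDataset:
    """Undo standardization, recovering the raw feature values."""
    stats = stats if stats is not None else dataset.norm_stats
    if stats is None:
        raise ConfigurationError("no normalization stats to invert with")
    frame = dataset.frame.copy()
    for name in FEATURE_NAMES:
        s = stats[name]
        frame[name] = frame[name].astype(float) * s["std"] + s["mean"]
    return LabeledDataset(frame, norm_stats=None)


def split_dataset(
    dataset: LabeledDataset,
    train_frac: float = 0.7,
    seed: int = 0,
    level: str = "sample",
) -> tuple[LabeledDataset, LabeledDataset]:
    """Random, reproducible train/test partition.

    ``level="sample"`` shuffles trials and puts ``floor(train_frac * N)``
    of them in the training split; ``level="subject"`` shuffles subjects
    and assigns whole subjects to the training split until it holds at
    least ``floor(train_frac * N)`` trials.
    """
    if not 0 < train_frac < 1:
        raise InvalidParameterError("train_frac must be in (0, 1)")
    if level not in ("sample", "subject"):
        raise InvalidParameterError(f"unknown split level {level!r}")
    n = dataset.n
    n_train = int(np.floor(train_frac * n))
    if n_train < 1 or n - n_train < 1:
        raise InsufficientDataError("dataset too small for a non-empty split")
    rng = np.random.default_rng(seed)
    if level == "sample":
        order = rng.permutation(n)
        train_idx, test_idx = order[:n_train], order[n_train:]
    else:
        if "subject_id" not in dataset.frame.columns:
            raise ConfigurationError("subject-level split needs a subject_id column")
        subjects = dataset.frame["subject_id"].to_numpy()
        unique = rng.permutation(pd.unique(subjects))
        train_subjects: list = []
        count = 0
        for s in unique:
            if count >= n_train:
                break
            train_subjects.append(s)
            count += int(np.sum(subjects == s))
        mask = np.isin(subjects, train_subjects)
        train_idx, test_idx = np.flatnonzero(mask), np.flatnonzero(~mask)
        if len(train_idx) == 0 or len(test_idx) == 0:
            raise InsufficientDataError("subject-level split left one part empty")
    make = lambda idx: LabeledDataset(
        dataset.frame.iloc[np.sort(idx)].reset_index(drop=True),
        norm_stats=dataset.norm_stats,
    )
    return make(train_idx), make(test_idx)


def save_stats(stats: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(stats, fh, indent=2)


def load_stats(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
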