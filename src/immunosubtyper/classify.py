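"""Random-forest subtype classification with min-max feature scaling.

Features are the per-signature enrichment scores, rescaled per feature to
[0, 1] by x' = (x - x_min) / (x_max - x_min) across the samples of a
cohort.  A 100-tree random forest is trained on the labeled cohort;
performance is measured by stratified 10-fold cross-validation (pooled
out-of-fold confusion matrix) and, for transfer to a new cohort, the new
cohort is rescaled by its own extrema before prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .scoring import SignatureScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedFeatureMatrix",
    "SubtypeClassifier",
    "EvalMetrics",
    "minmax_normalize",
    "train",
    "cross_validate",
    "predict",
    "confusion_matrix",
    "weighted_f_score",
    "metrics_from_confusion",
]


@dataclass(frozen=True)
class NormalizedFeatureMatrix:
    """Feature-by-sample matrix rescaled to [0, 1], with recorded extrema."""

    data: pd.DataFrame
    x_min: pd.Series
    x_max: pd.Series

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def apply_extrema(self, values: pd.Series | pd.DataFrame):
        """Rescale new values with this matrix's recorded extrema.

        Results outside [0, 1] are possible (the new values exceeded the
        recorded range) and are returned as-is alongside a boolean
        out-of-range mask.
        """
        span = (self.x_max - self.x_min).replace(0, np.nan)
        if isinstance(values, pd.Series):
            scaled = (values - self.x_min.loc[values.index]) / span.loc[values.index]
        else:
            scaled = values.sub(self.x_min.loc[values.index], axis=0).div(
                span.loc[values.index], axis=0
            )
        scaled = scaled.fillna(0.0)
        out_of_range = (scaled < 0) | (scaled > 1)
        return scaled, out_of_range


@dataclass(frozen=True)
class SubtypeClassifier:
    """Fitted random forest plus the metadata needed for safe reuse."""

    model: RandomForestClassifier
    feature_names: tuple[str, ...]
    class_labels: tuple[str, ...]
    n_trees: int
    seed: int


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion matrix (true x predicted) and the derived metrics."""

    confusion: pd.DataFrame
    accuracy: float
    weighted_f: float
    per_class: pd.DataFrame


def minmax_normalize(scores: SignatureScoreMatrix | pd.DataFrame) -> NormalizedFeatureMatrix:
    """Per-feature min-max rescaling across samples.

    A constant feature maps to all zeros with a warning; a single-sample
    matrix is an error (extrema would be degenerate by construction).
    """
    data = scores.data if isinstance(scores, SignatureScoreMatrix) else scores
    if data.shape[1] < 2:
        raise ValueError("min-max normalization needs >= 2 samples")
    x_min = data.min(axis=1)
    x_max = data.max(axis=1)
    span = x_max - x_min
    constant = span == 0
    if constant.any():
        logger.warning(
            "%d constant feature(s) mapped to all zeros: %s",
            int(constant.sum()),
            list(data.index[constant])[:5],
        )
    safe_span = span.replace(0, np.nan)
    norm = data.sub(x_min, axis=0).div(safe_span, axis=0).fillna(0.0)
    return NormalizedFeatureMatrix(data=norm, x_min=x_min, x_max=x_max)


def train(
    norm: NormalizedFeatureMatrix,
    labels: pd.Series,
    n_trees: int = 100,
    seed: int = 0,
) -> SubtypeClassifier:
    """Fit a random forest on normalized features.

    Only the tree count is pinned (100 by default); other hyperparameters
    stay at library defaults and are recoverable from the fitted model.
    Requires >= 2 classes with >= 2 samples each.
    """
    y = labels.loc[norm.sample_ids]
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("need >= 2 classes")
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"classes with a single sample: {list(small.index)}")
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    model.fit(norm.data.to_numpy().T, y.to_numpy())
    return SubtypeClassifier(
        model=model,
        feature_names=tuple(norm.feature_names),
        class_labels=tuple(model.classes_),
        n_trees=n_trees,
        seed=seed,
    )


def predict(model: SubtypeClassifier, norm_new: NormalizedFeatureMatrix) -> pd.Series:
    """Predict subtype labels for a (independently normalized) cohort.

    Features are matched by name, order-insensitively; missing features are
    an error listing their names.
    """
    missing = [f for f in model.feature_names if f not in norm_new.data.index]
    if missing:
        raise ValueError(f"cohort is missing features: {missing}")
    X = norm_new.data.loc[list(model.feature_names)].to_numpy().T
    pred = model.model.predict(X)
    return pd.Series(pred, index=norm_new.sample_ids, name="predicted_label")


def confusion_matrix(truth: pd.Series, predicted: pd.Series) -> pd.DataFrame:
    """True x predicted contingency table over the union of observed labels."""
    truth, predicted = truth.align(predicted, join="inner")
    labels = sorted(set(truth) | set(predicted))
    table = pd.crosstab(truth, predicted).reindex(
        index=labels, columns=labels, fill_value=0
    )
    table.index.name = "true"
    table.columns.name = "predicted"
    return table


def weighted_f_score(confusion: pd.DataFrame) -> float:
    """Support-weighted mean of per-class F1 scores.

    A class with no true positives and no predictions contributes F1 = 0.
    """
    arr = confusion.to_numpy(dtype=float)
    total = arr.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    supports = arr.sum(axis=1)
    f1s = np.zeros(len(arr))
    for i in range(len(arr)):
        tp = arr[i, i]
        denom = supports[i] + arr[:, i].sum()  # 2*tp + fn + fp
        f1s[i] = 2 * tp / denom if denom > 0 else 0.0
    if supports.sum() == 0:
        raise ValueError("no true samples in confusion matrix")
    return float((supports * f1s).sum() / supports.sum())


def metrics_from_confusion(confusion: pd.DataFrame) -> EvalMetrics:
    arr = confusion.to_numpy(dtype=float)
    total = arr.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(arr) / total)
    supports = arr.sum(axis=1)
    rows = []
    for i, label in enumerate(confusion.index):
        tp = arr[i, i]
        fp = arr[:, i].sum() - tp
        fn = supports[i] - tp
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        rows.append(
            {"class": label, "precision": precision, "recall": recall,
             "f1": f1, "support": int(supports[i])}
        )
    per_class = pd.DataFrame(rows).set_index("class")
    return EvalMetrics(
        confusion=confusion,
        accuracy=accuracy,
        weighted_f=weighted_f_score(confusion),
        per_class=per_class,
    )


def cross_validate(
    norm: NormalizedFeatureMatrix,
    labels: pd.Series,
    folds: int = 10,
    n_trees: int = 100,
    seed: int = 0,
) -> EvalMetrics:
    """Stratified k-fold cross-validation with pooled out-of-fold predictions.

    All out-of-fold predictions go into one confusion matrix from which the
    accuracy and weighted F-score are computed.  Every class must have at
    least ``folds`` members.
    """
    y = labels.loc[norm.sample_ids]
    X = norm.data.to_numpy().T
    y_arr = y.to_numpy()
    if folds == len(y_arr):
        # leave-one-out boundary: stratification is meaningless with
        # singleton test folds
        splits = LeaveOneOut().split(X)
    else:
        counts = y.value_counts()
        thin = counts[counts < folds]
        if len(thin):
            raise ValueError(
                f"classes smaller than fold count {folds}: {dict(thin)}; use fewer folds"
            )
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = skf.split(X, y_arr)
    pooled = pd.Series(index=norm.sample_ids, dtype=object)
    for train_idx, test_idx in splits:
        model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        model.fit(X[train_idx], y_arr[train_idx])
        pooled.iloc[test_idx] = model.predict(X[test_idx])
    return metrics_from_confusion(confusion_matrix(y, pooled))
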