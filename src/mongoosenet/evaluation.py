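"""Confusion counts, the three detection metrics, and evaluation protocols.

Class 1 (abnormal) is the positive class.  Accuracy, sensitivity
(true-positive rate) and specificity (true-negative rate) are

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

Two protocols: a stratified training-percentage split and stratified
k-fold cross-validation with confusion counts pooled over folds.  The
whole pipeline — normalization, imputation, feature selection, training —
is refitted inside each training portion, so no statistic leaks from
held-out patients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .classifier import build_pipeline
from .data import TabularDataset

__all__ = [
    "confusion_counts",
    "classification_metrics",
    "EvalReport",
    "split_eval",
    "kfold_eval",
]


def _check_binary(v, name: str) -> np.ndarray:
    v = np.asarray(v)
    if v.size < 1:
        raise ValueError(f"{name} must be non-empty")
    if not np.isin(v, [0, 1]).all():
        raise ValueError(f"{name} must contain only 0 and 1")
    return v.astype(int)


def confusion_counts(predicted, actual) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) with class 1 = abnormal = positive."""
    pred = _check_binary(predicted, "predicted")
    act = _check_binary(actual, "actual")
    if pred.size != act.size:
        raise ValueError("predicted and actual must have equal length")
    tp = int(np.sum((pred == 1) & (act == 1)))
    tn = int(np.sum((pred == 0) & (act == 0)))
    fp = int(np.sum((pred == 1) & (act == 0)))
    fn = int(np.sum((pred == 0) & (act == 1)))
    return tp, tn, fp, fn


def classification_metrics(
    tp: int, tn: int, fp: int, fn: int
) -> tuple[float, float | None, float | None]:
    """(accuracy, sensitivity, specificity).

    A metric whose denominator is zero is undefined and returned as
    ``None`` with a warning, never silently as 0.
    """
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("all confusion counts are zero")
    accuracy = (tp + tn) / total
    if tp + fn > 0:
        sensitivity = tp / (tp + fn)
    else:
        warnings.warn("no positive samples: sensitivity undefined")
        sensitivity = None
    if tn + fp > 0:
        specificity = tn / (tn + fp)
    else:
        warnings.warn("no negative samples: specificity undefined")
        specificity = None
    return accuracy, sensitivity, specificity


@dataclass
class EvalReport:
    """Confusion counts and metrics for one protocol setting."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    protocol: str          # "split" | "kfold"
    setting: float         # train fraction or k
    seed: int | None = None

    @classmethod
    def from_predictions(cls, predicted, actual, protocol: str, setting: float,
                         seed: int | None = None) -> "EvalReport":
        tp, tn, fp, fn = confusion_counts(predicted, actual)
        acc, sens, spec = classification_metrics(tp, tn, fp, fn)
        return cls(tp, tn, fp, fn, acc, sens, spec, protocol, setting, seed)

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol, "setting": self.setting, "seed": self.seed,
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def csv_row(self) -> str:
        """One-line CSV row for sweep aggregation."""
        vals = [self.protocol, self.setting, self.seed,
                self.accuracy, self.sensitivity, self.specificity]
        return ",".join("" if v is None else str(v) for v in vals)


def _make_pipeline(data: TabularDataset, pipeline_config: dict | None, seed: int | None):
    cfg = dict(pipeline_config or {})
    return build_pipeline(
        numeric_features=data.numeric_columns,
        categorical_features=data.categorical_columns,
        o=cfg.get("o"),
        z=cfg.get("z"),
        rank_by_abs=cfg.get("rank_by_abs", True),
        congruence_form=cfg.get("congruence_form", "tucker"),
        classifier_params=cfg.get("classifier"),
        random_state=seed,
    )


def split_eval(
    data: TabularDataset,
    train_fraction: float = 0.9,
    seed: int = 0,
    pipeline_config: dict | None = None,
) -> EvalReport:
    """Stratified train/test split at ``train_fraction``; fit on the
    training portion only, report held-out confusion and metrics."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    idx = np.arange(data.n_samples)
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=data.labels, random_state=seed
    )
    y_train = data.labels[train_idx]
    if np.unique(y_train).size < 2:
        raise ValueError("training split contains a single class; re-seed the split")
    pipe = _make_pipeline(data, pipeline_config, seed)
    pipe.fit(data.values[train_idx], y_train)
    pred = pipe.predict(data.values[test_idx])
    return EvalReport.from_predictions(
        pred, data.labels[test_idx], "split", train_fraction, seed
    )


def kfold_eval(
    data: TabularDataset,
    k: int = 9,
    seed: int = 0,
    pipeline_config: dict | None = None,
) -> EvalReport:
    """Stratified k-fold protocol; confusion counts pooled over folds and
    metrics computed once on the pooled counts."""
    if not 2 <= k <= data.n_samples:
        raise ValueError("k must lie in [2, n_samples]")
    minority = int(np.bincount(data.labels).min())
    if k > minority:
        raise ValueError(f"k={k} exceeds the minority-class count ({minority})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled_pred = np.empty(data.n_samples, dtype=int)
    for fold, (train_idx, test_idx) in enumerate(skf.split(data.values, data.labels)):
        pipe = _make_pipeline(data, pipeline_config, seed + fold)
        pipe.fit(data.values[train_idx], data.labels[train_idx])
        pooled_pred[test_idx] = pipe.predict(data.values[test_idx])
    return EvalReport.from_predictions(pooled_pred, data.labels, "kfold", k, seed)
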