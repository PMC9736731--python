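"""Random-Forest prediction of COL11A1 positivity from texture features.

A seeded Random Forest is trained on the full 212-feature panel of
labeled discovery tiles and applied to validation tiles.  Evaluation
supports two sensitivity/specificity conventions, because published
confusion matrices sometimes normalize by the predicted class rather
than the reference class:

* ``REFERENCE_DENOMINATOR`` (textbook): sensitivity = TP/(TP+FN),
  specificity = TN/(TN+FP).
* ``PREDICTED_DENOMINATOR``: "sensitivity" = TP/(TP+FP) (precision) and
  "specificity" = TN/(TN+FN) (negative predictive value).

Accuracy is identical under both.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "ForestConfig",
    "FittedForest",
    "MetricConvention",
    "ConfusionSummary",
    "train_forest",
    "predict",
    "predict_cores",
    "evaluate",
    "save_model",
    "load_model",
]


class MetricConvention(enum.Enum):
    REFERENCE_DENOMINATOR = "reference"
    PREDICTED_DENOMINATOR = "predicted"


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    max_features: str | int | float = "sqrt"
    max_depth: int | None = None
    bootstrap: bool = True
    seed: int = 0


@dataclass
class FittedForest:
    model: RandomForestClassifier
    feature_names: list[str]
    config: ForestConfig
    importances: pd.Series = field(repr=False, default=None)


def train_forest(features: pd.DataFrame, labels, config: ForestConfig = ForestConfig()) -> FittedForest:
    """Train a seeded forest on all features; importances are mean
    impurity decrease per named feature."""
    y = np.asarray(labels, dtype=bool)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if features.isna().any().any():
        raise ValueError("missing feature values in training table")
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        max_depth=config.max_depth,
        bootstrap=config.bootstrap,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(features.to_numpy(), y)
    imps = pd.Series(model.feature_importances_, index=features.columns).sort_values(ascending=False)
    return FittedForest(model=model, feature_names=list(features.columns), config=config, importances=imps)


def predict(fitted: FittedForest, features: pd.DataFrame) -> np.ndarray:
    """Per-tile binary calls (majority vote; ties break negative)."""
    missing = [c for c in fitted.feature_names if c not in features.columns]
    extra = [c for c in features.columns if c not in fitted.feature_names]
    if missing or extra:
        raise ValueError(f"feature schema mismatch: missing={missing[:5]} unexpected={extra[:5]}")
    x = features[fitted.feature_names].to_numpy()
    proba = fitted.model.predict_proba(x)
    pos_col = list(fitted.model.classes_).index(True)
    return proba[:, pos_col] > 0.5


def predict_cores(calls: np.ndarray, core_ids) -> pd.Series:
    """Core-level calls: a core is positive when any of its tiles is,
    mirroring the any-positive-cells scoring rule of core review."""
    return pd.Series(np.asarray(calls, bool)).groupby(np.asarray(core_ids)).any()


@dataclass
class ConfusionSummary:
    """Confusion counts plus rates under both metric conventions."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    def sensitivity(self, convention: MetricConvention = MetricConvention.REFERENCE_DENOMINATOR) -> float:
        if convention is MetricConvention.REFERENCE_DENOMINATOR:
            return self.tp / (self.tp + self.fn)
        return self.tp / (self.tp + self.fp)

    def specificity(self, convention: MetricConvention = MetricConvention.REFERENCE_DENOMINATOR) -> float:
        if convention is MetricConvention.REFERENCE_DENOMINATOR:
            return self.tn / (self.tn + self.fp)
        return self.tn / (self.tn + self.fn)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity_reference": self.sensitivity(MetricConvention.REFERENCE_DENOMINATOR),
            "specificity_reference": self.specificity(MetricConvention.REFERENCE_DENOMINATOR),
            "sensitivity_predicted": self.sensitivity(MetricConvention.PREDICTED_DENOMINATOR),
            "specificity_predicted": self.specificity(MetricConvention.PREDICTED_DENOMINATOR),
        }


def evaluate(calls, truth) -> ConfusionSummary:
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError(f"length mismatch: {calls.shape} calls vs {truth.shape} truth")
    return ConfusionSummary(
        tp=int(np.sum(calls & truth)),
        fp=int(np.sum(calls & ~truth)),
        tn=int(np.sum(~calls & ~truth)),
        fn=int(np.sum(~calls & truth)),
    )


def save_model(fitted: FittedForest, path) -> None:
    joblib.dump(
        {"model": fitted.model, "feature_names": fitted.feature_names, "config": fitted.config},
        path,
    )


def load_model(path) -> FittedForest:
    payload = joblib.load(path)
    fitted = FittedForest(
        model=payload["model"], feature_names=payload["feature_names"], config=payload["config"]
    )
    fitted.importances = pd.Series(
        fitted.model.feature_importances_, index=fitted.feature_names
    ).sort_values(ascending=False)
    return fitted
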