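"""Random-forest and feed-forward neural-network nodule classifiers.

Both classifiers consume the 28-entry feature vector.  The random forest
is a bagged ensemble of decision trees with sqrt-feature subsampling;
the ANN is a single-hidden-layer perceptron with a logistic output.
ANN features are z-scored with statistics computed on the training split
only, so no information leaks from held-out data; trees are
scale-invariant and receive raw features.

Evaluation uses stratified k-fold cross-validation with independently
trained per-fold models; the pooled confusion counts feed the metric
suite.  The positive class throughout is "malignant".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .errors import FormatError, TrainingError
from .metrics import ConfusionCounts, confusion

POSITIVE_CLASS = "malignant"

DEFAULT_RF_PARAMS: dict = {"n_estimators": 100, "max_features": "sqrt"}
DEFAULT_ANN_PARAMS: dict = {
    "hidden_layer_sizes": (16,),
    "activation": "logistic",
    "max_iter": 2000,
}


@dataclass
class LabeledDataset:
    """Feature matrix with class labels and sample identifiers."""

    features: np.ndarray
    labels: np.ndarray
    ids: np.ndarray

    @classmethod
    def from_table(cls, table: pd.DataFrame, label_column: str = "label",
                   id_column: str | None = None) -> "LabeledDataset":
        feats = table.drop(columns=[c for c in (label_column, id_column)
                                    if c is not None and c in table.columns])
        ids = (table[id_column].to_numpy() if id_column and id_column in table
               else np.arange(len(table)))
        return cls(features=feats.to_numpy(dtype=np.float64),
                   labels=table[label_column].to_numpy(),
                   ids=np.asarray(ids))

    def validate(self, for_training: bool = True) -> None:
        X = np.asarray(self.features, dtype=np.float64)
        if X.ndim != 2:
            raise FormatError(f"features must be 2-D, got shape {X.shape}")
        if not np.all(np.isfinite(X)):
            raise TrainingError("feature matrix contains missing/non-finite values")
        if len(self.labels) != X.shape[0]:
            raise FormatError("labels and features disagree in length")
        if for_training and len(np.unique(self.labels)) < 2:
            raise TrainingError("training data must contain both classes")


@dataclass
class TrainedModel:
    """A fitted classifier plus its (training-split-only) normalisation."""

    kind: str
    estimator: object
    feature_mean: np.ndarray | None
    feature_std: np.ndarray | None
    classes: np.ndarray
    n_features: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return X
        return (X - self.feature_mean) / self.feature_std


def train(
    data: LabeledDataset,
    kind: str = "rf",
    hyperparams: dict | None = None,
    rng_seed: int = 0,
) -> TrainedModel:
    """Fit a classifier of the requested kind on the full dataset.

    ``kind`` is "rf" (random forest, raw features) or "ann" (multilayer
    perceptron on z-scored features).  A fixed ``rng_seed`` makes the
    fitted model, and hence its predictions, reproducible.
    """
    data.validate(for_training=True)
    X = np.asarray(data.features, dtype=np.float64)
    y = np.asarray(data.labels)

    if kind == "rf":
        params = {**DEFAULT_RF_PARAMS, **(hyperparams or {})}
        est = RandomForestClassifier(random_state=rng_seed, **params)
        mean = std = None
        Xt = X
    elif kind == "ann":
        params = {**DEFAULT_ANN_PARAMS, **(hyperparams or {})}
        est = MLPClassifier(random_state=rng_seed, **params)
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std > 0, std, 1.0)  # constant features stay centred
        Xt = (X - mean) / std
    else:
        raise TrainingError(f"kind must be 'rf' or 'ann', got {kind!r}")

    est.fit(Xt, y)
    return TrainedModel(kind=kind, estimator=est, feature_mean=mean,
                        feature_std=std, classes=np.asarray(est.classes_),
                        n_features=X.shape[1])


def predict(model: TrainedModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and malignancy scores in [0, 1] for a feature matrix."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise FormatError(
            f"expected {model.n_features} features per sample, got {X.shape[1]}"
        )
    Xt = model.transform(X)
    labels = model.estimator.predict(Xt)
    proba = model.estimator.predict_proba(Xt)
    if POSITIVE_CLASS in model.classes:
        pos_idx = int(np.where(model.classes == POSITIVE_CLASS)[0][0])
    else:
        pos_idx = proba.shape[1] - 1
    return labels, proba[:, pos_idx]


@dataclass
class CVResult:
    """Outcome of a stratified k-fold run."""

    fold_counts: list[ConfusionCounts]
    pooled: ConfusionCounts
    predictions: np.ndarray
    fold_index: np.ndarray  # test-fold assignment per sample
    scores: np.ndarray

    @property
    def pooled_accuracy(self) -> float:
        cc = self.pooled
        return (cc.tp + cc.tn) / cc.total


def cross_validate(
    data: LabeledDataset,
    kind: str = "rf",
    k: int = 5,
    rng_seed: int = 0,
    hyperparams: dict | None = None,
    positive_class: str = POSITIVE_CLASS,
) -> CVResult:
    """Stratified k-fold cross-validation with per-fold models.

    Each fold's model (and, for the ANN, its z-scoring statistics) is fit
    on the training portion only.  Returns fold-wise and pooled confusion
    counts; pooled counts partition the dataset exactly.
    """
    data.validate(for_training=True)
    if k < 2:
        raise TrainingError(f"need k >= 2 folds, got {k}")
    y = np.asarray(data.labels)
    _, class_counts = np.unique(y, return_counts=True)
    if class_counts.min() < k:
        raise TrainingError(
            f"stratified {k}-fold needs >= {k} samples per class, "
            f"smallest class has {class_counts.min()}"
        )

    X = np.asarray(data.features, dtype=np.float64)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
    predictions = np.empty(len(y), dtype=y.dtype)
    scores = np.empty(len(y), dtype=np.float64)
    fold_index = np.empty(len(y), dtype=np.int64)
    fold_counts: list[ConfusionCounts] = []

    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        sub = LabeledDataset(features=X[train_idx], labels=y[train_idx],
                             ids=np.asarray(data.ids)[train_idx])
        model = train(sub, kind=kind, hyperparams=hyperparams,
                      rng_seed=rng_seed + fold)
        pred, score = predict(model, X[test_idx])
        predictions[test_idx] = pred
        scores[test_idx] = score
        fold_index[test_idx] = fold
        fold_counts.append(confusion(y[test_idx], pred, positive_class))

    pooled = ConfusionCounts(
        tp=sum(c.tp for c in fold_counts),
        fp=sum(c.fp for c in fold_counts),
        fn=sum(c.fn for c in fold_counts),
        tn=sum(c.tn for c in fold_counts),
    )
    return CVResult(fold_counts=fold_counts, pooled=pooled,
                    predictions=predictions, fold_index=fold_index,
                    scores=scores)


def save_model(model: TrainedModel, path) -> None:
    """Serialise a trained model (versioned joblib file)."""
    import joblib

    joblib.dump({"format_version": 1, "model": model}, path)


def load_model(path) -> TrainedModel:
    import joblib

    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise FormatError(f"unsupported model file version in {path}")
    return payload["model"]
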