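"""Classifiers for binary AS-vs-QS staging: the 1-D CNN plus six benchmarks.

QS is the positive class throughout (it is the minority class). Benchmarks
consume each 8x60 epoch flattened to a 480-vector and standardized per
training fold; the CNN consumes the 8x60 tensor directly. Inverse-frequency
class weights (w_c = N / (2 N_c)) are computed from training data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._cnn import CNNClassifier, CNNConfig
from .types import FeatureEpoch

BENCHMARK_IDS = ("KNN", "NB", "SVM", "RF", "AdaB", "XGB")

POSITIVE_CLASS = "QS"

#: How the published hyperparameter names map onto the estimators used here.
#: XGBoost itself is replaced by sklearn gradient boosting with the same
#: printed learning rate and depth (no xgboost runtime dependency).
COMPAT_TABLE: dict[str, str] = {
    "KNN": "n_neighbors=20; 'squared inverse' distance weight -> weights=1/d^2; "
           "'Exhaustive' neighbor search -> algorithm='brute'; no class weighting "
           "(KNN supports none).",
    "NB": "GaussianNB (normal-kernel naive Bayes); the 0.05 kernel width has no "
          "sklearn equivalent and is absorbed by the per-fold standardization.",
    "SVM": "linear kernel; box constraint -> C=0.1; kernel scale is a no-op for "
           "the linear kernel; probability estimates via Platt scaling.",
    "RF": "n_estimators=100, max_depth=20, min_samples_split=2 (verbatim).",
    "AdaB": "learning_rate=0.5; base tree with min_samples_leaf=8 and "
            "max_leaf_nodes=21 (max splits 20).",
    "XGB": "GradientBoostingClassifier(learning_rate=0.2, max_depth=3) standing "
           "in for XGBoost with its printed hyperparameters.",
}


@dataclass
class ClassWeights:
    """Inverse-frequency class weights; positive class is QS."""

    weights: dict[str, float]

    @classmethod
    def from_labels(cls, labels: list[str] | np.ndarray) -> "ClassWeights":
        labels = list(labels)
        counts = {c: labels.count(c) for c in ("AS", "QS")}
        if min(counts.values()) == 0:
            missing = [c for c, n in counts.items() if n == 0]
            raise ValueError(f"training set has no {missing[0]} epochs; "
                             "both classes are required")
        n = len(labels)
        return cls(weights={c: n / (2.0 * k) for c, k in counts.items()})

    def as_binary(self) -> dict[int, float]:
        """{0: w_AS, 1: w_QS} for estimators indexing classes numerically."""
        return {0: self.weights["AS"], 1: self.weights["QS"]}


@dataclass
class BenchmarkSpec:
    """One of the six benchmark classifiers with its published hyperparameters."""

    classifier_id: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    search_grid: dict[str, list] | None = None  # optional GridSearchCV grid
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier_id not in BENCHMARK_IDS:
            raise ValueError(
                f"unknown classifier id {self.classifier_id!r}; "
                f"expected one of {BENCHMARK_IDS}"
            )


def _squared_inverse(distances: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        w = 1.0 / distances**2
    # an exact-match neighbor gets all the weight
    inf_rows = np.isinf(w).any(axis=1)
    w[inf_rows] = np.isinf(w[inf_rows]).astype(float)
    return w


def make_estimator(spec: BenchmarkSpec, class_weight: dict[int, float] | None = None):
    """Instantiate the sklearn estimator for a benchmark spec."""
    hp = spec.hyperparameters
    cid = spec.classifier_id
    if cid == "KNN":
        est = KNeighborsClassifier(
            n_neighbors=hp.get("n_neighbors", 20),
            weights=_squared_inverse, algorithm="brute",
        )
    elif cid == "NB":
        est = GaussianNB()
    elif cid == "SVM":
        est = SVC(kernel=hp.get("kernel", "linear"), C=hp.get("C", 0.1),
                  probability=True, class_weight=class_weight,
                  random_state=spec.seed)
    elif cid == "RF":
        est = RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100),
            max_depth=hp.get("max_depth", 20),
            min_samples_split=hp.get("min_samples_split", 2),
            class_weight=class_weight, random_state=spec.seed,
        )
    elif cid == "AdaB":
        base = DecisionTreeClassifier(
            min_samples_leaf=hp.get("min_samples_leaf", 8),
            max_leaf_nodes=hp.get("max_leaf_nodes", 21),
            random_state=spec.seed,
        )
        est = AdaBoostClassifier(estimator=base,
                                 learning_rate=hp.get("learning_rate", 0.5),
                                 random_state=spec.seed)
    else:  # XGB stand-in
        est = GradientBoostingClassifier(
            learning_rate=hp.get("learning_rate", 0.2),
            max_depth=hp.get("max_depth", 3),
            random_state=spec.seed,
        )
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


def stack_epochs(epochs: list[FeatureEpoch]) -> tuple[np.ndarray, np.ndarray]:
    """(N, 8, 60) tensor and binary labels (1 = QS)."""
    X = np.stack([e.matrix for e in epochs])
    y = np.array([1 if e.label == POSITIVE_CLASS else 0 for e in epochs])
    return X, y


@dataclass
class TrainedModel:
    """A fitted classifier plus the metadata needed to audit it."""

    model_id: str
    estimator: Any
    class_weights: ClassWeights | None = None
    fold_id: int | None = None
    seed: int = 0
    is_cnn: bool = False
    loss_trace: list[float] = field(default_factory=list)

    def predict_proba(self, epochs: list[FeatureEpoch] | np.ndarray) -> np.ndarray:
        """Probability of QS per epoch; hard labels use threshold 0.5
        (exactly 0.5 goes to the negative class)."""
        X = epochs if isinstance(epochs, np.ndarray) else stack_epochs(epochs)[0]
        if self.is_cnn:
            p = self.estimator.predict_proba(X)
        else:
            p = self.estimator.predict_proba(X.reshape(len(X), -1))[:, 1]
        if np.any((p < 0) | (p > 1)):
            raise ValueError("estimator produced out-of-range probabilities")
        return p

    def predict(self, epochs: list[FeatureEpoch] | np.ndarray) -> np.ndarray:
        return (self.predict_proba(epochs) > 0.5).astype(int)


def compute_class_weights(labels: list[str] | np.ndarray) -> ClassWeights:
    return ClassWeights.from_labels(labels)


def train_cnn(epochs: list[FeatureEpoch], config: CNNConfig | None = None,
              weights: ClassWeights | None = None, fold_id: int | None = None
              ) -> TrainedModel:
    X, y = stack_epochs(epochs)
    _require_both_classes(y)
    weights = weights or ClassWeights.from_labels([e.label for e in epochs])
    cfg = config or CNNConfig()
    clf = CNNClassifier(cfg).fit(X, y, class_weights=weights.as_binary())
    return TrainedModel(model_id="CNN", estimator=clf, class_weights=weights,
                        fold_id=fold_id, seed=cfg.seed, is_cnn=True,
                        loss_trace=clf.loss_trace)


def train_benchmark(epochs: list[FeatureEpoch], spec: BenchmarkSpec,
                    weights: ClassWeights | None = None, fold_id: int | None = None
                    ) -> TrainedModel:
    X, y = stack_epochs(epochs)
    _require_both_classes(y)
    weights = weights or ClassWeights.from_labels([e.label for e in epochs])
    cw = weights.as_binary()
    pipe = make_estimator(spec, class_weight=cw)
    Xf = X.reshape(len(X), -1)
    fit_kwargs = {}
    # class weights go through class_weight where the estimator has it,
    # through sample_weight otherwise; KNN supports neither (documented)
    if spec.classifier_id in ("NB", "AdaB", "XGB"):
        fit_kwargs["clf__sample_weight"] = np.array([cw[int(t)] for t in y])
    if spec.search_grid:
        from sklearn.model_selection import GridSearchCV

        grid = {f"clf__{k}": v for k, v in spec.search_grid.items()}
        search = GridSearchCV(pipe, grid, cv=3, scoring="balanced_accuracy")
        search.fit(Xf, y, **fit_kwargs)
        pipe = search.best_estimator_
    else:
        pipe.fit(Xf, y, **fit_kwargs)
    return TrainedModel(model_id=spec.classifier_id, estimator=pipe,
                        class_weights=weights, fold_id=fold_id, seed=spec.seed)


def _require_both_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both AS and QS epochs")


def default_model_specs(seed: int = 0) -> list[BenchmarkSpec]:
    return [BenchmarkSpec(classifier_id=cid, seed=seed) for cid in BENCHMARK_IDS]
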