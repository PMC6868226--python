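"""Stratified splitting, multiclass SVM training, and cross-validation.

Grading is a three-class problem (good / moderate / unhealthy).  Features
are z-scored with training statistics and fed to an RBF-kernel support
vector machine in the one-vs-one multiclass scheme; per-class decision
scores are obtained by vote-margin aggregation of the pairwise machines
(the usual one-vs-rest aggregation), which is what the precision-recall
curves are computed from.

Hyperparameters (C and the kernel width) are selected by grid search under
k-fold cross-validation on the training partition only.  Leave-one-out
cross-validation (k equal to the training-set size) is available via
``cv="loo"`` or ``cross_validate(..., k=n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import (
    GridSearchCV,
    KFold,
    LeaveOneOut,
    StratifiedKFold,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "LabeledFeatureSet",
    "SvmConfig",
    "ClassifierModel",
    "stratified_split",
    "train_classifier",
    "predict",
    "cross_validate",
]


@dataclass
class LabeledFeatureSet:
    """Aligned (features, labels, ids) triple for n samples."""

    features: np.ndarray  # (n, p)
    labels: np.ndarray  # (n,) strings
    ids: np.ndarray  # (n,) strings

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.ids = np.asarray(self.ids)
        n = self.features.shape[0]
        if len(self.labels) != n or len(self.ids) != n:
            raise ValueError("features, labels and ids must align row-wise")

    def __len__(self) -> int:
        return self.features.shape[0]

    def subset(self, idx: np.ndarray) -> "LabeledFeatureSet":
        return LabeledFeatureSet(
            self.features[idx], self.labels[idx], self.ids[idx]
        )


@dataclass
class SvmConfig:
    """RBF-SVM training configuration.

    The kernel-width grid is expressed as multiples of 1/p (p = feature
    dimension): gamma in {2^-4 ... 2^2} / p.
    """

    C_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    gamma_scale_grid: tuple = tuple(2.0**k for k in range(-4, 3))
    cv: int | str = 5  # fold count, or "loo" for leave-one-out
    seed: int = 0


@dataclass
class ClassifierModel:
    """A fitted scaler + multiclass SVM with its selected hyperparameters."""

    pipeline: Pipeline
    classes: np.ndarray
    best_params: dict = field(default_factory=dict)
    cv_score: float = float("nan")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(
    dataset: LabeledFeatureSet,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[LabeledFeatureSet, LabeledFeatureSet]:
    """Per-class random split into train and test partitions.

    Each class contributes ``round(train_fraction * n_c)`` samples to the
    training set (281 per class at 0.7 gives the canonical 197/84).  The
    split is a partition and is deterministic for a fixed seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(dataset.labels):
        idx = np.nonzero(dataset.labels == cls)[0]
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        rng.shuffle(idx)
        n_train = _round_half_up(train_fraction * len(idx))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return dataset.subset(np.sort(train_idx)), dataset.subset(
        np.sort(test_idx)
    )


def _make_pipeline(C: float, gamma: float) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel="rbf",
                    C=C,
                    gamma=gamma,
                    decision_function_shape="ovr",
                ),
            ),
        ]
    )


def train_classifier(
    train: LabeledFeatureSet, config: SvmConfig | None = None
) -> ClassifierModel:
    """Grid-searched RBF SVM on z-scored training features.

    Model selection uses stratified k-fold (or leave-one-out) on the
    training partition only; the winning model is refit on all of it.
    """
    config = config or SvmConfig()
    X, y = train.features, train.labels
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if not np.all(np.isfinite(X)):
        raise ValueError("training features must be finite")
    p = X.shape[1]
    param_grid = {
        "svm__C": list(config.C_grid),
        "svm__gamma": [g / p for g in config.gamma_scale_grid],
    }
    if config.cv == "loo":
        cv = LeaveOneOut()
    else:
        n_min = min(np.sum(y == c) for c in classes)
        cv = StratifiedKFold(
            n_splits=min(int(config.cv), int(n_min)),
            shuffle=True,
            random_state=config.seed,
        )
    search = GridSearchCV(
        _make_pipeline(1.0, 1.0 / p),
        param_grid,
        cv=cv,
        scoring="accuracy",
        n_jobs=1,
        refit=True,
    )
    search.fit(X, y)
    return ClassifierModel(
        pipeline=search.best_estimator_,
        classes=search.best_estimator_.named_steps["svm"].classes_,
        best_params=dict(search.best_params_),
        cv_score=float(search.best_score_),
    )


def predict(
    model: ClassifierModel, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and per-class decision scores for a feature matrix.

    Scores have one column per class (in ``model.classes`` order) from
    one-vs-rest aggregation of the one-vs-one machines, and are suitable
    for threshold sweeps (precision-recall curves).
    """
    features = np.asarray(features, dtype=float)
    p_expected = model.pipeline.named_steps["scale"].mean_.shape[0]
    if features.ndim != 2 or features.shape[1] != p_expected:
        raise ValueError(
            f"expected (n, {p_expected}) features, got {features.shape}"
        )
    labels = model.pipeline.predict(features)
    scores = model.pipeline.decision_function(features)
    if scores.ndim == 1:  # binary: expand to one column per class
        scores = np.column_stack([-scores, scores])
    return labels, scores


def cross_validate(
    dataset: LabeledFeatureSet,
    k: int | None = None,
    C: float = 10.0,
    gamma: float | None = None,
    seed: int = 0,
) -> dict:
    """k-fold cross-validation of the SVM at fixed hyperparameters.

    With ``k`` equal to the sample count (the default) this is
    leave-one-out: every sample is validated exactly once by a model fit
    on the remaining n-1.  Returns per-fold accuracies and their mean.
    """
    n = len(dataset)
    if k is None:
        k = n
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}], got {k}")
    gamma = gamma if gamma is not None else 1.0 / dataset.features.shape[1]
    if k == n:
        splitter = LeaveOneOut()
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for tr, va in splitter.split(dataset.features):
        pipe = _make_pipeline(C, gamma)
        pipe.fit(dataset.features[tr], dataset.labels[tr])
        pred = pipe.predict(dataset.features[va])
        accs.append(float(np.mean(pred == dataset.labels[va])))
    return {
        "k": k,
        "fold_accuracies": np.array(accs),
        "mean_accuracy": float(np.mean(accs)),
    }
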