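"""Classifier benchmarking under leave-one-out and k-fold protocols.

Four classifiers at published settings:

* SVM — RBF kernel, C = 1, gamma = 1/n_features,
* KNN — k = 5, Euclidean distance, majority vote with ties broken by the
  single nearest neighbour's class,
* Random Forest — 100 trees, bootstrap sampling, random feature subsets,
  random_state = 0,
* MLP — one hidden layer of 10 rectifier units, softmax output, full-batch
  gradient descent at learning rate 0.01 for 500 epochs.

Evaluation always tests *original* samples only: when an augmented block is
supplied it is appended to every training fold, never to a test fold. Folds
pool their predictions into a single confusion matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, LeaveOneOut
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from swpkit.errors import ConfigError, DataError
from swpkit.evaluate import ClassificationReport, confusion_and_metrics
from swpkit.io import CONDITIONS

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS: tuple[str, ...] = ("svm", "knn", "random_forest", "mlp")


class TieBreakKNN(BaseEstimator, ClassifierMixin):
    """k-nearest-neighbour vote with ties broken by the nearest neighbour.

    Euclidean distance; ``k`` is clamped to the training-set size with a
    warning when the fold is smaller than ``k``.
    """

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.shape[0] == 0:
            raise DataError("empty training set")
        k = self.k
        if k > X.shape[0]:
            warnings.warn(
                f"k={k} exceeds training size {X.shape[0]}; clamping", stacklevel=2
            )
            k = X.shape[0]
        self.k_ = k
        self.classes_ = np.unique(y)
        self._nn = NearestNeighbors(n_neighbors=k).fit(X)
        self._y = y
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        _, idx = self._nn.kneighbors(X)  # neighbours sorted by distance
        out = np.empty(X.shape[0], dtype=object)
        for i, nbrs in enumerate(idx):
            labels = self._y[nbrs]
            values, counts = np.unique(labels, return_counts=True)
            best = counts.max()
            tied = set(values[counts == best])
            if len(tied) == 1:
                out[i] = next(iter(tied))
            else:
                out[i] = next(lab for lab in labels if lab in tied)
        return out


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to run and with what hyperparameters.

    ``params`` overrides the published defaults of the chosen kind.
    """

    kind: str = "random_forest"
    params: dict = field(default_factory=dict)
    standardize: bool = False  # optional z-scoring (off: traces are in [-1,1])

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ConfigError(
                f"unknown classifier {self.kind!r}; choose from {CLASSIFIER_KINDS}"
            )

    def build(self, seed: int = 0):
        p = dict(self.params)
        if self.kind == "svm":
            return SVC(C=p.pop("C", 1.0), kernel="rbf", gamma=p.pop("gamma", "auto"), **p)
        if self.kind == "knn":
            return TieBreakKNN(k=p.pop("k", 5))
        if self.kind == "random_forest":
            return RandomForestClassifier(
                n_estimators=p.pop("n_estimators", 100),
                random_state=p.pop("random_state", 0),
                **p,
            )
        # mlp: one hidden layer of 10 relu units, softmax via log-loss,
        # full-batch plain gradient descent, fixed 500 epochs
        max_iter = p.pop("max_iter", 500)
        return MLPClassifier(
            hidden_layer_sizes=p.pop("hidden_layer_sizes", (10,)),
            activation="relu",
            solver="sgd",
            learning_rate_init=p.pop("learning_rate_init", 0.01),
            momentum=0.0,
            nesterovs_momentum=False,
            batch_size=p.pop("batch_size", 2**30),  # clamped to n_samples: full batch
            max_iter=max_iter,
            n_iter_no_change=max_iter,
            tol=0.0,
            random_state=p.pop("random_state", seed),
            **p,
        )


@dataclass(frozen=True)
class SplitProtocol:
    """How folds are drawn and where augmented samples may appear."""

    kind: str = "loocv"
    folds: int = 5
    train_only_augmentation: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("loocv", "kfold"):
            raise ConfigError("protocol kind must be 'loocv' or 'kfold'")
        if self.kind == "kfold" and self.folds < 2:
            raise ConfigError("kfold needs folds >= 2")

    def splitter(self, n: int, seed: int):
        if self.kind == "loocv":
            return LeaveOneOut().split(np.arange(n))
        kf = KFold(n_splits=self.folds, shuffle=True, random_state=seed)
        return kf.split(np.arange(n))


def run_classification(
    X,
    y,
    spec: ClassifierSpec = ClassifierSpec(),
    protocol: SplitProtocol = SplitProtocol(),
    X_aug=None,
    y_aug=None,
    seed: int = 0,
    classes=None,
) -> ClassificationReport:
    """Cross-validated classification with optional training-set augmentation.

    For each fold the classifier trains on the fold's original training rows
    plus (when supplied and ``train_only_augmentation`` is set) *all*
    augmented rows; predictions on the held-out originals are pooled across
    folds into one confusion matrix. With ``train_only_augmentation`` off,
    augmented rows join the cross-validation pool and are split like
    originals (predictions are still pooled over every test row).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DataError("X must be 2-D with one label per row")
    have_aug = X_aug is not None and len(X_aug) > 0
    if have_aug:
        X_aug = np.asarray(X_aug, dtype=float)
        y_aug = np.asarray(y_aug, dtype=object)
        if X_aug.shape[1] != X.shape[1]:
            raise DataError(
                f"augmented feature width {X_aug.shape[1]} != original {X.shape[1]}"
            )
    observed = set(y) | set(y_aug if have_aug else [])
    if classes is None:
        # condition labels keep their canonical order; anything else sorts
        classes = CONDITIONS if observed <= set(CONDITIONS) else tuple(sorted(observed))
    classes = tuple(c for c in classes if c in observed)

    if have_aug and not protocol.train_only_augmentation:
        X = np.vstack([X, X_aug])
        y = np.concatenate([y, y_aug])
        have_aug = False

    y_true_all, y_pred_all = [], []
    for train_idx, test_idx in protocol.splitter(X.shape[0], seed):
        X_tr, y_tr = X[train_idx], y[train_idx]
        if have_aug:
            X_tr = np.vstack([X_tr, X_aug])
            y_tr = np.concatenate([y_tr, y_aug])
        missing = set(classes) - set(y_tr)
        if missing:
            warnings.warn(
                f"training fold lacks class(es) {sorted(missing)}", stacklevel=2
            )
        X_te = X[test_idx]
        if spec.standardize:
            scaler = StandardScaler().fit(X_tr)
            X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        clf = spec.build(seed=seed)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
            warnings.filterwarnings("ignore", message=".*batch_size.*")
            clf.fit(X_tr, y_tr)
        y_pred_all.extend(np.asarray(clf.predict(X_te), dtype=object))
        y_true_all.extend(y[test_idx])
    return confusion_and_metrics(y_true_all, y_pred_all, classes)


def run_grid(
    feature_sets: dict,
    spec_kinds=CLASSIFIER_KINDS,
    protocol: SplitProtocol = SplitProtocol(),
    augmented_feature_sets: dict | None = None,
    seed: int = 0,
) -> dict:
    """One report per (feature kind, classifier kind, augmentation method).

    Parameters
    ----------
    feature_sets : dict
        ``{feature_kind: (X, y)}`` of original samples.
    augmented_feature_sets : dict, optional
        ``{method: {feature_kind: (X_aug, y_aug)}}``; each method adds a grid
        column; ``None`` entries mean classification on originals only.

    Returns
    -------
    dict mapping ``(feature_kind, classifier_kind, method)`` to a
    :class:`~swpkit.evaluate.ClassificationReport` (method ``"none"`` for the
    unaugmented cells). Failing cells are stored as the raised exception so
    the rest of the grid completes.
    """
    if not feature_sets:
        raise ConfigError("feature_sets must not be empty")
    methods: dict = {"none": None}
    if augmented_feature_sets:
        methods.update(augmented_feature_sets)
    grid: dict = {}
    for feat_kind, (X, y) in feature_sets.items():
        for clf_kind in spec_kinds:
            for method, aug in methods.items():
                key = (feat_kind, clf_kind, method)
                try:
                    X_aug = y_aug = None
                    if aug is not None:
                        X_aug, y_aug = aug[feat_kind]
                    grid[key] = run_classification(
                        X, y, ClassifierSpec(kind=clf_kind), protocol,
                        X_aug=X_aug, y_aug=y_aug, seed=seed,
                    )
                except Exception as exc:  # complete the remaining cells
                    logger.warning("grid cell %s failed: %s", key, exc)
                    grid[key] = exc
    return grid


def grid_to_frame(grid: dict):
    """Tidy accuracy table: rows = classifier, columns = feature x method."""
    import pandas as pd

    rows = {}
    for (feat, clf, method), report in grid.items():
        acc = report.accuracy if isinstance(report, ClassificationReport) else np.nan
        rows.setdefault(clf, {})[(feat, method)] = acc
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["feature", "method"])
    return frame.sort_index(axis=1)
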