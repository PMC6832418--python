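"""Supervised multiclass models over multiscale point-cloud features.

Four model families are supported, each configured the way the method
fixes them rather than tuned per dataset:

* ``lda`` — linear discriminant analysis (closed-form, no hyperparameters);
* ``lr`` — multinomial logistic regression, plain maximum likelihood
  (no regularization penalty);
* ``svm`` — RBF-kernel support vector machine, ``C = 10``,
  ``gamma = 0.01``, one-against-one multiclass decomposition;
* ``rf`` — random forest of 50 trees, Gini split criterion, bootstrap
  resampling, nodes grown without depth or leaf limits.

The estimator binds feature column names at fit time and refuses
prediction inputs whose columns differ — a guard against mixing feature
matrices extracted with different scale ladders.
"""

from __future__ import annotations

from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PointCloudClassifier",
    "balanced_sample",
    "save_model",
    "load_model",
    "MODEL_FAMILIES",
]

MODEL_FAMILIES = ("lda", "lr", "svm", "rf")

_MODEL_FILE_FORMAT = "mscloud-model-v1"


def balanced_sample(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    per_class: int,
    seed: int | None = None,
) -> tuple[pd.DataFrame | np.ndarray, np.ndarray, np.ndarray]:
    """Draw a class-balanced training subset without replacement.

    For each class, ``min(per_class, available)`` rows are drawn uniformly.
    Returns ``(features_subset, labels_subset, row_indices)``; deterministic
    for a fixed ``seed``.
    """
    if labels is None:
        raise ValueError("balanced sampling requires labels")
    labels = np.asarray(labels)
    n = len(labels)
    if hasattr(features, "shape") and features.shape[0] != n:
        raise ValueError("features and labels must have equal length")
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    rng = np.random.default_rng(seed)
    picked = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        take = min(per_class, len(idx))
        picked.append(rng.choice(idx, size=take, replace=False))
    index = np.sort(np.concatenate(picked))
    subset = (
        features.iloc[index]
        if isinstance(features, pd.DataFrame)
        else np.asarray(features)[index]
    )
    return subset, labels[index], index


class PointCloudClassifier(ClassifierMixin, BaseEstimator):
    """Multiclass classifier over per-point feature matrices.

    Parameters
    ----------
    family : {"lda", "lr", "svm", "rf"}, default "rf"
        Model family.
    n_trees : int, default 50
        Forest size (``rf`` only).
    svm_c, svm_gamma : float, defaults 10.0 and 0.01
        RBF-SVM regularization and kernel width (``svm`` only).
    standardize : bool, default False
        Z-score features at fit time and apply the same transform at
        predict time.  Off by default; the fixed ``svm_gamma`` is only
        meaningful relative to raw feature magnitudes, so scaling is an
        explicit, visible switch rather than an implicit step.
    random_state : int or None
        Seed for the forest's bootstrap/feature subsampling.  Fixing it
        makes ``rf`` predictions exactly reproducible; the other three
        families are deterministic up to solver tolerance anyway.

    Attributes
    ----------
    model_ : fitted underlying estimator
    classes_ : array of class labels seen at fit
    feature_names_ : list of column names bound at fit time
    scaler_ : fitted StandardScaler or None
    """

    def __init__(
        self,
        family: str = "rf",
        n_trees: int = 50,
        svm_c: float = 10.0,
        svm_gamma: float = 0.01,
        standardize: bool = False,
        random_state: int | None = None,
    ):
        self.family = family
        self.n_trees = n_trees
        self.svm_c = svm_c
        self.svm_gamma = svm_gamma
        self.standardize = standardize
        self.random_state = random_state

    # -- construction ------------------------------------------------------

    def _make_model(self):
        if self.family == "lda":
            return LinearDiscriminantAnalysis()
        if self.family == "lr":
            # C=inf: plain maximum likelihood, no regularization penalty
            return LogisticRegression(C=np.inf, max_iter=2000)
        if self.family == "svm":
            # SVC trains one binary problem per class pair (one-against-one)
            return SVC(kernel="rbf", C=self.svm_c, gamma=self.svm_gamma)
        if self.family == "rf":
            return RandomForestClassifier(
                n_estimators=self.n_trees,
                criterion="gini",
                bootstrap=True,
                random_state=self.random_state,
            )
        raise ValueError(
            f"unknown model family {self.family!r}; "
            f"expected one of {MODEL_FAMILIES}"
        )

    @staticmethod
    def _coerce(X) -> tuple[np.ndarray, list[str] | None]:
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=np.float64), list(X.columns)
        return np.asarray(X, dtype=np.float64), None

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y, feature_names: list[str] | None = None):
        """Fit the configured family on a feature matrix and labels."""
        values, cols = self._coerce(X)
        if values.ndim != 2:
            raise ValueError("X must be a 2D feature matrix")
        y = np.asarray(y)
        if y.shape[0] != values.shape[0]:
            raise ValueError("X and y must have equal length")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature matrix contains non-finite values")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError(
                "training set contains a single class; at least 2 required"
            )

        self.feature_names_ = list(
            feature_names
            if feature_names is not None
            else cols
            if cols is not None
            else [f"f{i}" for i in range(values.shape[1])]
        )
        if len(self.feature_names_) != values.shape[1]:
            raise ValueError("feature_names length does not match X columns")

        if self.standardize:
            self.scaler_ = StandardScaler().fit(values)
            values = self.scaler_.transform(values)
        else:
            self.scaler_ = None

        self.model_ = self._make_model()
        self.model_.fit(values, y)
        self.classes_ = self.model_.classes_
        return self

    def _validate_predict_input(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        values, cols = self._coerce(X)
        if cols is not None and cols != self.feature_names_:
            extra = [c for c in cols if c not in self.feature_names_]
            missing = [c for c in self.feature_names_ if c not in cols]
            raise ValueError(
                "feature columns do not match the columns bound at fit "
                f"time (missing: {missing}, unexpected: {extra})"
            )
        if values.shape[1] != len(self.feature_names_):
            raise ValueError(
                f"expected {len(self.feature_names_)} feature columns "
                f"({self.feature_names_}), got {values.shape[1]}"
            )
        if self.scaler_ is not None:
            values = self.scaler_.transform(values)
        return values

    def predict(self, X) -> np.ndarray:
        """Hard class label per row."""
        values = self._validate_predict_input(X)
        return self.model_.predict(values)

    def predict_proba(self, X) -> np.ndarray:
        """Per-class probabilities (lda, lr, rf; the SVM is not probabilistic)."""
        if self.family == "svm":
            raise AttributeError(
                "the SVM assigns classes directly and does not expose "
                "probabilities"
            )
        values = self._validate_predict_input(X)
        return self.model_.predict_proba(values)

    def _more_tags(self):  # pragma: no cover - sklearn plumbing
        return {"requires_y": True}


# ---------------------------------------------------------------------------
# Single-file model artifacts
# ---------------------------------------------------------------------------

def save_model(clf: PointCloudClassifier, path: str | Path) -> None:
    """Serialize a fitted classifier (family, params, columns, state)."""
    check_is_fitted(clf, "model_")
    joblib.dump(
        {
            "format": _MODEL_FILE_FORMAT,
            "params": clf.get_params(),
            "feature_names": clf.feature_names_,
            "classes": clf.classes_,
            "scaler": clf.scaler_,
            "model": clf.model_,
        },
        path,
    )


def load_model(path: str | Path) -> PointCloudClassifier:
    """Load a classifier saved by :func:`save_model`."""
    blob = joblib.load(path)
    if blob.get("format") != _MODEL_FILE_FORMAT:
        raise ValueError(
            f"{path}: not a recognized model file "
            f"(format tag {blob.get('format')!r})"
        )
    clf = PointCloudClassifier(**blob["params"])
    clf.feature_names_ = blob["feature_names"]
    clf.classes_ = blob["classes"]
    clf.scaler_ = blob["scaler"]
    clf.model_ = blob["model"]
    return clf


def fresh_clone(clf: PointCloudClassifier) -> PointCloudClassifier:
    """Unfitted copy with identical configuration."""
    return clone(clf)
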