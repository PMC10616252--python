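"""Gradient-boosted classifier for selenium-absorption efficiency.

A scikit-learn compatible wrapper around XGBoost exposing exactly the
hyperparameters the pipeline tunes (tree depth, learning rate, number of
boosting rounds, L2 penalty) plus split-count ("weight") feature
importances, so it composes with sklearn cross-validation and grid
search.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier


def labels_to_binary(y) -> np.ndarray:
    """Map LE/HE class labels to 0/1 with HE as the positive class.
    Numeric binary labels pass through unchanged."""
    arr = np.asarray(y)
    if arr.dtype.kind in "OUS":
        vals = set(np.unique(arr).tolist())
        if not vals <= {"LE", "HE"}:
            raise ValueError(f"expected LE/HE labels, got {sorted(vals)}")
        return (arr == "HE").astype(int)
    return arr.astype(int)


class SeleniumEfficiencyClassifier(ClassifierMixin, BaseEstimator):
    """Binary gradient-boosted decision-tree classifier (XGBoost backend).

    Parameters
    ----------
    n_estimators : int
        Boosting rounds.
    max_depth : int
        Maximum tree depth.
    learning_rate : float
        Shrinkage per round.
    reg_lambda : float
        L2 penalty on leaf weights (the model-side half of the "L2
        regularization" used when fusing host features).
    random_state : int
        Seed; together with single-threaded histogram training this makes
        fits bit-reproducible.
    """

    def __init__(self, n_estimators: int = 100, max_depth: int = 3,
                 learning_rate: float = 0.3, reg_lambda: float = 1.0,
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.reg_lambda = reg_lambda
        self.random_state = random_state

    def _make_backend(self) -> XGBClassifier:
        return XGBClassifier(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            learning_rate=self.learning_rate, reg_lambda=self.reg_lambda,
            random_state=self.random_state, tree_method="hist", n_jobs=1,
            eval_metric="logloss", verbosity=0)

    def fit(self, X, y):
        y = labels_to_binary(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need both classes present to fit")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.values
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.asarray(
                [f"f{i}" for i in range(X.shape[1])], dtype=object)
        self.n_features_in_ = X.shape[1]
        self.model_ = self._make_backend()
        self.model_.fit(X, y)
        return self

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X.values
        return np.asarray(X, dtype=float)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._matrix(X))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    def decision_scores(self, X) -> np.ndarray:
        """Probability of the positive (HE) class."""
        return self.predict_proba(X)[:, 1]

    def feature_importances(self, importance_type: str = "weight"
                            ) -> pd.Series:
        """Per-feature importance; ``weight`` counts how many tree splits
        use the feature (``gain`` is available behind the flag).
        Features never used by any split get 0."""
        check_is_fitted(self, "model_")
        booster = self.model_.get_booster()
        raw = booster.get_score(importance_type=importance_type)
        scores = np.zeros(self.n_features_in_)
        for key, val in raw.items():
            scores[int(key[1:])] = val
        return pd.Series(scores, index=self.feature_names_in_,
                         name=importance_type)
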