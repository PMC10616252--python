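"""Biomarker ranking and refinement.

Genera are ranked by their split-count ("weight") importance in a
gradient-boosted classifier trained on all genera; a learning curve over
the top-k prefixes locates the refinement point, and the top-k genera
(k = 10 by default) become the biomarker set.  Batch-specific biomarker
sets are intersected to obtain region/batch-stable shared biomarkers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .estimator import SeleniumEfficiencyClassifier, labels_to_binary

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 10


@dataclass
class BiomarkerRanking:
    """Genera ordered by non-increasing importance; ties broken
    lexicographically by genus name."""

    entries: list[tuple[str, float]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        names = [g for g, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate genus in ranking")
        scores = [s for _, s in self.entries]
        if any(s < 0 for s in scores):
            raise ValueError("importance scores must be non-negative")
        if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genus_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    def top(self, k: int) -> list[str]:
        return self.genus_ids[:k]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.entries, columns=["genus", "importance"])
        df.index.name = "rank"
        return df

    @classmethod
    def from_scores(cls, scores: pd.Series,
                    provenance: dict | None = None) -> "BiomarkerRanking":
        order = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(entries=[(g, float(s)) for g, s in order],
                   provenance=provenance or {})


def rank_features(X: pd.DataFrame, y, hyperparams: dict | None = None,
                  seed: int = 0,
                  importance_type: str = "weight") -> BiomarkerRanking:
    """Rank features by classifier importance.

    Fits the gradient-boosted classifier on all columns of `X` and sorts
    features by descending importance (split count by default), breaking
    ties lexicographically.  Deterministic given `seed`.
    """
    y = labels_to_binary(y)
    if len(np.unique(y)) < 2:
        raise ValueError("rank_features needs both classes present")
    if len(y) < 10:
        raise ValueError("rank_features needs at least 10 samples")
    clf = SeleniumEfficiencyClassifier(**(hyperparams or {}),
                                       random_state=seed)
    clf.fit(X, y)
    scores = clf.feature_importances(importance_type=importance_type)
    return BiomarkerRanking.from_scores(
        scores, provenance={"seed": seed, "n_samples": len(y),
                            "hyperparams": clf.get_params(),
                            "importance_type": importance_type})


def _cv(y: np.ndarray, cv_folds: int, seed: int) -> StratifiedKFold:
    min_class = int(np.bincount(y).min())
    folds = cv_folds
    if folds > min_class:
        warnings.warn(f"reducing cv_folds from {cv_folds} to {min_class} "
                      "(smallest class count)", stacklevel=3)
        folds = min_class
    if folds < 2:
        raise ValueError("not enough samples per class for cross-validation")
    return StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)


def learning_curve(ranking: BiomarkerRanking, X: pd.DataFrame, y,
                   k_values: list[int], cv_folds: int = 5,
                   seed: int = 0,
                   hyperparams: dict | None = None) -> list[tuple[int, float]]:
    """Mean cross-validated AUC of the top-k model, per k.

    Retrains the classifier on the top-k ranked features for each k in
    `k_values` under stratified k-fold CV; the refinement point is where
    this curve plateaus.
    """
    y = labels_to_binary(y)
    if any(k < 1 or k > len(ranking) for k in k_values):
        raise ValueError("k_values must lie within [1, len(ranking)]")
    cv = _cv(y, cv_folds, seed)
    out = []
    for k in k_values:
        cols = ranking.top(k)
        clf = SeleniumEfficiencyClassifier(**(hyperparams or {}),
                                           random_state=seed)
        aucs = cross_val_score(clf, X.loc[:, cols], y, cv=cv,
                               scoring="roc_auc")
        out.append((k, float(aucs.mean())))
    return out


def select_biomarkers(ranking: BiomarkerRanking,
                      k: int = DEFAULT_TOP_K) -> list[str]:
    """The top-k ranked genera (the 'biomarkers')."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds ranking length {len(ranking)}")
    return ranking.top(k)


def shared_biomarkers(rankings: list[BiomarkerRanking],
                      k: int = DEFAULT_TOP_K) -> set[str]:
    """Genera common to every ranking's top-k set (Venn intersection
    across batches/cohorts); empty intersection is allowed but warned."""
    if len(rankings) < 2:
        raise ValueError("shared_biomarkers needs at least 2 rankings")
    sets = [set(r.top(k)) for r in rankings]
    shared = set.intersection(*sets)
    if not shared:
        warnings.warn("no biomarker shared across all rankings", stacklevel=2)
    return shared
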