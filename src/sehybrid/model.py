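"""Training, transfer, hybrid calibration and cross-cohort refinement.

The central objects are the :class:`FeatureRecipe` — the exact mapping
from a (abundance table, metadata) pair to the model's feature matrix
(genus subset, one-hot encoding spec, row L2 normalization) — and the
:class:`ModelBundle`, a fitted classifier together with its recipe, so
the same model can be applied verbatim to a new sequencing batch or
cohort.

Two transfer protocols are implemented:

* **hybrid calibration** — mix a small number n of new-batch samples
  into the training data, retrain with the bundle's hyperparameters and
  evaluate on a held-out fraction of the new batch, repeated over
  randomizations; the AUC-versus-n curve shows how many new samples are
  needed to absorb a batch effect.
* **cross-cohort refinement** — rebuild the model keeping only genera
  whose biomarker status is shared across batches/regions (host
  metadata still encoded and fused), then evaluate on the other
  region's cohort.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid, cross_val_score
from xgboost import Booster

from .data import AbundanceTable
from .encoding import EncodingSpec, fuse_and_normalize, one_hot_encode
from .estimator import SeleniumEfficiencyClassifier, labels_to_binary
from .features import _cv

logger = logging.getLogger(__name__)

#: Hyperparameter search space for the heuristic 5-fold CV tuning.
DEFAULT_SEARCH_SPACE = {
    "max_depth": [2, 3, 4],
    "learning_rate": [0.1, 0.3],
    "n_estimators": [100],
    "reg_lambda": [1.0, 10.0],
}

DEFAULT_N_MIX = [5, 10, 15, 20, 25, 30]


# ---------------------------------------------------------------------------
# feature recipe / bundle
# ---------------------------------------------------------------------------

@dataclass
class FeatureRecipe:
    """Deterministic mapping from raw tables to the model's features.

    Genus columns come first (in the stored order); genera absent from a
    target table are zero-filled (and logged), extra genera are ignored.
    When `use_metadata`, the one-hot host columns follow and each row is
    L2-normalized.
    """

    genus_subset: list[str]
    encoding: EncodingSpec = field(default_factory=EncodingSpec)
    use_metadata: bool = True
    normalize: bool = True

    def build(self, table: AbundanceTable,
              meta: pd.DataFrame | None = None) -> pd.DataFrame:
        missing = [g for g in self.genus_subset if g not in table.data.columns]
        if missing:
            logger.info("recipe: zero-filling %d genera absent from target: %s",
                        len(missing), missing)
        X = table.data.reindex(columns=self.genus_subset, fill_value=0.0)
        if self.use_metadata:
            if meta is None:
                raise ValueError("recipe requires host metadata")
            encoded = one_hot_encode(meta.loc[X.index], self.encoding)
            if self.normalize:
                return fuse_and_normalize(X, encoded)
            return pd.concat([X, encoded], axis=1)
        if self.normalize:
            return fuse_and_normalize(X, pd.DataFrame(index=X.index))
        return X

    def to_dict(self) -> dict:
        return {"genus_subset": list(self.genus_subset),
                "encoding": asdict(self.encoding),
                "use_metadata": self.use_metadata,
                "normalize": self.normalize}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureRecipe":
        return cls(genus_subset=list(d["genus_subset"]),
                   encoding=EncodingSpec(**d["encoding"]),
                   use_metadata=bool(d["use_metadata"]),
                   normalize=bool(d["normalize"]))


@dataclass
class ModelBundle:
    """A fitted classifier plus everything needed to re-apply or retrain it."""

    model: SeleniumEfficiencyClassifier
    recipe: FeatureRecipe
    hyperparams: dict
    seed: int
    source: str = ""
    cv_auc: float | None = None
    training_scores: pd.Series | None = None

    def predict_scores(self, table: AbundanceTable,
                       meta: pd.DataFrame | None = None) -> pd.Series:
        X = self.recipe.build(table, meta)
        return pd.Series(self.model.decision_scores(X), index=X.index,
                         name="score")

    # -- serialization: directory of text artifacts ------------------------
    def save(self, path) -> None:
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        self.model.model_.get_booster().save_model(str(out / "model.json"))
        with open(out / "recipe.yaml", "w") as fh:
            yaml.safe_dump(self.recipe.to_dict(), fh, sort_keys=False)
        prov = {"hyperparams": self.hyperparams, "seed": self.seed,
                "source": self.source, "cv_auc": self.cv_auc}
        (out / "provenance.json").write_text(json.dumps(prov, indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "ModelBundle":
        src = Path(path)
        with open(src / "recipe.yaml") as fh:
            recipe = FeatureRecipe.from_dict(yaml.safe_load(fh))
        prov = json.loads((src / "provenance.json").read_text())
        clf = SeleniumEfficiencyClassifier(**prov["hyperparams"],
                                           random_state=prov["seed"])
        clf.model_ = clf._make_backend()
        booster = Booster()
        booster.load_model(str(src / "model.json"))
        clf.model_._Booster = booster
        clf.model_.n_classes_ = 2
        clf.classes_ = np.array([0, 1])
        clf.n_features_in_ = len(recipe.genus_subset) + (
            recipe.encoding.n_columns() if recipe.use_metadata else 0)
        clf.feature_names_in_ = np.asarray(
            [f"f{i}" for i in range(clf.n_features_in_)], dtype=object)
        return cls(model=clf, recipe=recipe, hyperparams=prov["hyperparams"],
                   seed=prov["seed"], source=prov.get("source", ""),
                   cv_auc=prov.get("cv_auc"))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    auc: float | None
    scores: pd.Series
    class_counts: dict[str, int]
    provenance: dict = field(default_factory=dict)
    valid: bool = True


def auc_from_scores(y_true, scores) -> float:
    """AUC by the rank (Mann-Whitney) definition; tied scores count 0.5."""
    return float(roc_auc_score(labels_to_binary(y_true), np.asarray(scores)))


def evaluate_scores(y_true, scores: pd.Series,
                    provenance: dict | None = None) -> EvaluationReport:
    y = labels_to_binary(y_true)
    counts = {"LE": int((y == 0).sum()), "HE": int((y == 1).sum())}
    if counts["LE"] == 0 or counts["HE"] == 0:
        warnings.warn("single-class test set: AUC undefined", stacklevel=2)
        return EvaluationReport(auc=None, scores=scores, class_counts=counts,
                                provenance=provenance or {}, valid=False)
    return EvaluationReport(auc=auc_from_scores(y, scores), scores=scores,
                            class_counts=counts,
                            provenance=provenance or {})


def evaluate_auc(model, X_test, y_test,
                 provenance: dict | None = None) -> EvaluationReport:
    """Evaluate a fitted classifier (or bundle model) on a feature matrix."""
    clf = model.model if isinstance(model, ModelBundle) else model
    idx = X_test.index if isinstance(X_test, pd.DataFrame) else range(len(X_test))
    scores = pd.Series(clf.decision_scores(X_test), index=idx, name="score")
    return evaluate_scores(y_test, scores, provenance)


# ---------------------------------------------------------------------------
# tuning / training
# ---------------------------------------------------------------------------

def tune_and_train(X: pd.DataFrame, y, search_space: dict | None = None,
                   cv_folds: int = 5, seed: int = 0
                   ) -> tuple[SeleniumEfficiencyClassifier, dict, float]:
    """Heuristic grid search maximizing mean CV AUC, then refit on all data.

    Returns ``(fitted classifier, best hyperparameters, best mean CV
    AUC)``.  The grid order is deterministic, ties keep the first
    configuration, and all fits share `seed`, so the selection is
    reproducible.
    """
    y = labels_to_binary(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to train")
    if X.shape[1] > 0 and (np.asarray(X) == np.asarray(X)[0]).all():
        warnings.warn("all feature columns are constant", stacklevel=2)
    space = search_space or DEFAULT_SEARCH_SPACE
    cv = _cv(y, cv_folds, seed)
    best_params, best_auc = None, -np.inf
    for params in ParameterGrid(space):
        clf = SeleniumEfficiencyClassifier(**params, random_state=seed)
        auc = float(cross_val_score(clf, X, y, cv=cv, scoring="roc_auc").mean())
        if auc > best_auc:
            best_params, best_auc = params, auc
    clf = SeleniumEfficiencyClassifier(**best_params, random_state=seed)
    clf.fit(X, y)
    return clf, dict(best_params), best_auc


def train_bundle(table: AbundanceTable, meta: pd.DataFrame | None, y,
                 genus_subset: list[str] | None = None,
                 encoding: EncodingSpec | None = None,
                 use_metadata: bool = True,
                 hyperparams: dict | None = None,
                 search_space: dict | None = None,
                 cv_folds: int = 5, seed: int = 0,
                 source: str = "") -> ModelBundle:
    """Build the feature recipe, (optionally) tune, and fit a bundle.

    If `hyperparams` is given the grid search is skipped and those
    parameters are used directly (the CV AUC is still computed for the
    record).
    """
    recipe = FeatureRecipe(
        genus_subset=list(genus_subset) if genus_subset is not None
        else list(table.genus_ids),
        encoding=encoding or EncodingSpec(),
        use_metadata=use_metadata)
    X = recipe.build(table, meta)
    yb = labels_to_binary(y)
    if hyperparams is not None:
        cv = _cv(yb, cv_folds, seed)
        clf = SeleniumEfficiencyClassifier(**hyperparams, random_state=seed)
        cv_auc = float(cross_val_score(clf, X, yb, cv=cv,
                                       scoring="roc_auc").mean())
        clf.fit(X, yb)
        best = dict(hyperparams)
    else:
        clf, best, cv_auc = tune_and_train(X, yb, search_space=search_space,
                                           cv_folds=cv_folds, seed=seed)
    scores = pd.Series(clf.decision_scores(X), index=X.index, name="score")
    return ModelBundle(model=clf, recipe=recipe, hyperparams=best, seed=seed,
                       source=source, cv_auc=cv_auc, training_scores=scores)


def transfer_evaluate(bundle: ModelBundle, table: AbundanceTable,
                      meta: pd.DataFrame | None, y) -> EvaluationReport:
    """Apply a bundle verbatim to a new batch/cohort and evaluate.

    The recipe handles feature harmonization: genera missing from the
    target are zero-filled, extra genera ignored.
    """
    scores = bundle.predict_scores(table, meta)
    return evaluate_scores(y, scores,
                           provenance={"model": bundle.source,
                                       "n_test": len(scores)})


# ---------------------------------------------------------------------------
# hybrid calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """Mean/spread of test AUC versus number of new-batch samples mixed
    into the training data."""

    points: list[dict]          # n_mixed, auc_mean, auc_sd, n_repeats
    test_fraction: float
    seed: int

    def __post_init__(self):
        ns = [p["n_mixed"] for p in self.points]
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise ValueError("n_mixed must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points)

    def mean_auc(self, n_mixed: int) -> float:
        for p in self.points:
            if p["n_mixed"] == n_mixed:
                return p["auc_mean"]
        raise KeyError(n_mixed)


def calibrate_hybrid(base_X: pd.DataFrame, base_y, new_X: pd.DataFrame,
                     new_y, n_mix_values: list[int] | None = None,
                     test_fraction: float = 0.3, n_repeats: int = 5,
                     hyperparams: dict | None = None,
                     seed: int = 0) -> CalibrationCurve:
    """Hybrid cross-batch calibration.

    Per randomization repeat: hold out ``round(test_fraction * n_new)``
    new-batch samples as the test set, then for each n in `n_mix_values`
    draw n calibration samples from the remaining new-batch samples,
    retrain from scratch on base + calibration samples (fixed
    hyperparameters — the curve is attributable to data mixing alone)
    and evaluate on the held-out test set.  Calibration and test sets
    are disjoint by construction in every repeat.  Feature matrices must
    already be on the recipe's common column set.
    """
    if list(base_X.columns) != list(new_X.columns):
        raise ValueError("base and new-batch feature columns differ")
    n_mix_values = sorted(set(n_mix_values if n_mix_values is not None
                              else DEFAULT_N_MIX))
    base_y = labels_to_binary(base_y)
    new_y = labels_to_binary(new_y)
    if len(np.unique(new_y)) < 2:
        raise ValueError("new batch must contain both classes")
    n_new = len(new_X)
    n_test = int(round(test_fraction * n_new))
    if n_test < 1:
        raise ValueError("test fraction leaves no test samples")
    max_feasible = n_new - n_test
    hp = hyperparams or {}

    per_n: dict[int, list[float]] = {n: [] for n in n_mix_values}
    rng = np.random.default_rng(seed)
    for rep in range(n_repeats):
        order = rng.permutation(n_new)
        test_idx = order[:n_test]
        pool = order[n_test:]
        logger.info("calibrate repeat %d: test=%s", rep,
                    list(new_X.index[test_idx]))
        y_test = new_y[test_idx]
        X_test = new_X.iloc[test_idx]
        for n in n_mix_values:
            if n > len(pool):
                warnings.warn(f"n_mix={n} exceeds available remainder "
                              f"({len(pool)}); point skipped", stacklevel=2)
                continue
            cal_idx = rng.choice(pool, size=n, replace=False) if n > 0 \
                else np.array([], dtype=int)
            assert not set(cal_idx) & set(test_idx)
            X_tr = pd.concat([base_X, new_X.iloc[cal_idx]])
            y_tr = np.concatenate([base_y, new_y[cal_idx]])
            clf = SeleniumEfficiencyClassifier(**hp, random_state=seed)
            clf.fit(X_tr, y_tr)
            if len(np.unique(y_test)) < 2:
                continue  # AUC undefined for this repeat's draw
            per_n[n].append(auc_from_scores(y_test,
                                            clf.decision_scores(X_test)))

    points = []
    for n in n_mix_values:
        aucs = per_n[n]
        if not aucs:
            if n > max_feasible:
                continue
            raise RuntimeError(f"no valid repeat produced an AUC at n={n}")
        points.append({"n_mixed": int(n), "auc_mean": float(np.mean(aucs)),
                       "auc_sd": float(np.std(aucs, ddof=1)) if len(aucs) > 1
                       else 0.0,
                       "n_repeats": len(aucs)})
    return CalibrationCurve(points=points, test_fraction=test_fraction,
                            seed=seed)


# ---------------------------------------------------------------------------
# cross-cohort refinement
# ---------------------------------------------------------------------------

def cross_cohort_refine(base_table: AbundanceTable, base_meta: pd.DataFrame,
                        base_y, shared_genera, target_table: AbundanceTable,
                        target_meta: pd.DataFrame, target_y,
                        encoding: EncodingSpec | None = None,
                        hyperparams: dict | None = None,
                        cv_folds: int = 5,
                        seed: int = 0) -> EvaluationReport:
    """Retrain on the base cohort keeping only batch/region-shared genera
    (host metadata still encoded and fused), evaluate on the target cohort."""
    shared = sorted(shared_genera)
    if not shared:
        raise ValueError("shared gene set is empty — run shared_biomarkers "
                         "across the batch rankings first")
    absent = [g for g in shared if g not in base_table.data.columns]
    if absent:
        raise ValueError(f"shared genera absent from base cohort: {absent}")
    bundle = train_bundle(base_table, base_meta, base_y, genus_subset=shared,
                          encoding=encoding, hyperparams=hyperparams,
                          cv_folds=cv_folds, seed=seed,
                          source="cross_cohort_refined")
    report = transfer_evaluate(bundle, target_table, target_meta, target_y)
    report.provenance["shared_genera"] = shared
    report.provenance["base_cv_auc"] = bundle.cv_auc
    return report
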