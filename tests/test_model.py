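import logging

import numpy as np
import pandas as pd
import pytest

from sehybrid import AbundanceTable, EncodingSpec, calibrate_hybrid, \
    cross_cohort_refine, evaluate_auc, train_bundle, transfer_evaluate, \
    tune_and_train
from sehybrid.model import ModelBundle, auc_from_scores, evaluate_scores

from conftest import HP, TINY_SPACE, make_cohort


def pairwise_auc_oracle(y, scores):
    """Exhaustive Mann-Whitney AUC: P(score_HE > score_LE) + 0.5 ties."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAucEvaluation:
    def test_perfect_separation(self):
        rep = evaluate_scores(np.array([1, 1, 0, 0]),
                              pd.Series([0.9, 0.8, 0.1, 0.2]))
        assert rep.auc == 1.0

    def test_all_ties_give_half(self):
        rep = evaluate_scores(np.array([1, 1, 0, 0]),
                              pd.Series([0.5, 0.5, 0.5, 0.5]))
        assert rep.auc == 0.5

    def test_three_quarters_case(self):
        # HE (0.8, 0.4) vs LE (0.6, 0.2): 3 of 4 pairs won
        rep = evaluate_scores(np.array([1, 1, 0, 0]),
                              pd.Series([0.8, 0.4, 0.6, 0.2]))
        assert rep.auc == 0.75

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 51))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            scores = np.round(rng.random(n), 2)  # induce ties
            assert auc_from_scores(y, scores) == pytest.approx(
                pairwise_auc_oracle(y, scores), abs=1e-12)

    def test_single_class_flagged(self):
        with pytest.warns(UserWarning, match="single-class"):
            rep = evaluate_scores(np.ones(3, dtype=int),
                                  pd.Series([0.1, 0.2, 0.3]))
        assert not rep.valid and rep.auc is None


class TestTuneAndTrain:
    def test_deterministic_selection(self, single_batch_cohort):
        table, meta, _, labels = single_batch_cohort
        X = table.data.iloc[:, :15]
        _, p1, a1 = tune_and_train(X, labels, cv_folds=3, seed=9)
        _, p2, a2 = tune_and_train(X, labels, cv_folds=3, seed=9)
        assert p1 == p2 and a1 == a2

    def test_separable_data_high_auc(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = (X["f0"] > 0).astype(int)
        _, _, auc = tune_and_train(X, y, search_space=TINY_SPACE, seed=0)
        assert auc >= 0.95

    def test_label_permuted_null(self, single_batch_cohort):
        table, _, _, labels = single_batch_cohort
        y = (labels == "HE").astype(int).values
        aucs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            _, _, auc = tune_and_train(table.data, r.permutation(y),
                                       search_space=TINY_SPACE, seed=seed)
            aucs.append(auc)
        assert abs(np.median(aucs) - 0.5) <= 0.07

    def test_constant_features_warn(self):
        X = pd.DataFrame(np.ones((20, 3)), columns=list("abc"))
        y = np.array([0, 1] * 10)
        with pytest.warns(UserWarning, match="constant"):
            tune_and_train(X, y, search_space=TINY_SPACE, cv_folds=2, seed=0)


@pytest.fixture(scope="module")
def bundle_setup():
    table, meta, truth, labels = make_cohort(seed=11)
    bundle = train_bundle(table, meta, labels,
                          genus_subset=truth.signal_genera,
                          hyperparams=HP, seed=11, source="test")
    return table, meta, labels, bundle


class TestModelBundle:
    def test_training_predictions_reproduced(self, bundle_setup):
        table, meta, labels, bundle = bundle_setup
        scores = bundle.predict_scores(table, meta)
        np.testing.assert_array_equal(scores.values,
                                      bundle.training_scores.values)

    def test_transfer_to_training_set_is_identity(self, bundle_setup):
        table, meta, labels, bundle = bundle_setup
        rep = transfer_evaluate(bundle, table, meta, labels)
        assert rep.auc == auc_from_scores(labels, bundle.training_scores)

    def test_save_load_roundtrip(self, bundle_setup, tmp_path):
        table, meta, labels, bundle = bundle_setup
        bundle.save(tmp_path / "bundle")
        back = ModelBundle.load(tmp_path / "bundle")
        np.testing.assert_allclose(back.predict_scores(table, meta).values,
                                   bundle.predict_scores(table, meta).values,
                                   atol=1e-7)
        assert back.hyperparams == bundle.hyperparams

    def test_missing_genera_zero_filled(self, bundle_setup, caplog):
        table, meta, labels, bundle = bundle_setup
        keep = [g for g in table.genus_ids
                if g not in bundle.recipe.genus_subset[:3]]
        reduced = AbundanceTable(table.data.loc[:, keep])
        with caplog.at_level(logging.INFO, logger="sehybrid.model"):
            rep = transfer_evaluate(bundle, reduced, meta, labels)
        assert rep.valid
        assert "zero-filling 3 genera" in caplog.text

    def test_extra_genera_ignored(self, bundle_setup):
        table, meta, labels, bundle = bundle_setup
        extra = table.data.copy()
        extra["g__Novel"] = 0.01
        X = bundle.recipe.build(AbundanceTable(extra), meta)
        assert "g__Novel" not in X.columns
        assert list(X.columns[:len(bundle.recipe.genus_subset)]) == \
            bundle.recipe.genus_subset
        rep = transfer_evaluate(bundle, AbundanceTable(extra), meta, labels)
        assert rep.valid


@pytest.fixture(scope="module")
def two_batches():
    table, meta, truth, labels = make_cohort(
        seed=2, n_samples_per_batch=[120, 43], n_batches=2,
        batch_to_region={0: 0, 1: 0}, batch_shift_sd=1.0)
    bundle = train_bundle(
        table.subset_samples(meta.index[meta.batch == "B1"]),
        meta[meta.batch == "B1"], labels[meta.batch == "B1"],
        genus_subset=truth.signal_genera, hyperparams=HP, seed=2)
    b1 = meta.index[meta.batch == "B1"]
    b2 = meta.index[meta.batch == "B2"]
    X1 = bundle.recipe.build(table.subset_samples(b1), meta.loc[b1])
    X2 = bundle.recipe.build(table.subset_samples(b2), meta.loc[b2])
    return X1, labels.loc[b1], X2, labels.loc[b2], bundle, \
        table.subset_samples(b2), meta.loc[b2]


class TestCalibrateHybrid:
    def test_curve_structure(self, two_batches):
        X1, y1, X2, y2, bundle, *_ = two_batches
        cal = calibrate_hybrid(X1, y1, X2, y2, n_mix_values=[5, 15, 25],
                               hyperparams=HP, seed=0)
        ns = [p["n_mixed"] for p in cal.points]
        assert ns == [5, 15, 25]
        for p in cal.points:
            assert 0.0 <= p["auc_mean"] <= 1.0 and p["n_repeats"] >= 1

    def test_zero_mix_matches_plain_transfer(self, two_batches):
        X1, y1, X2, y2, bundle, t2, m2 = two_batches
        cal = calibrate_hybrid(X1, y1, X2, y2, n_mix_values=[0],
                               hyperparams=HP, n_repeats=10, seed=0)
        plain = transfer_evaluate(bundle, t2, m2, y2).auc
        point = cal.points[0]
        spread = max(0.1, 3 * point["auc_sd"])
        assert abs(point["auc_mean"] - plain) <= spread

    def test_infeasible_n_skipped_with_warning(self, two_batches):
        X1, y1, X2, y2, *_ = two_batches
        with pytest.warns(UserWarning, match="exceeds available"):
            cal = calibrate_hybrid(X1, y1, X2, y2, n_mix_values=[5, 40],
                                   hyperparams=HP, seed=0)
        assert [p["n_mixed"] for p in cal.points] == [5]

    def test_mismatched_columns_rejected(self, two_batches):
        X1, y1, X2, y2, *_ = two_batches
        with pytest.raises(ValueError, match="columns differ"):
            calibrate_hybrid(X1, y1, X2.iloc[:, ::-1], y2, hyperparams=HP)


class TestCrossCohortRefine:
    def test_full_set_on_base_equals_in_cohort(self):
        table, meta, truth, labels = make_cohort(seed=4)
        shared = truth.signal_genera
        rep = cross_cohort_refine(table, meta, labels, shared, table, meta,
                                  labels, hyperparams=HP, seed=4)
        bundle = train_bundle(table, meta, labels,
                              genus_subset=sorted(shared),
                              hyperparams=HP, seed=4)
        assert rep.auc == auc_from_scores(labels, bundle.training_scores)

    def test_empty_shared_set_rejected(self):
        table, meta, _, labels = make_cohort(seed=4, n_samples_per_batch=[40])
        with pytest.raises(ValueError, match="shared_biomarkers"):
            cross_cohort_refine(table, meta, labels, [], table, meta, labels)

    def test_absent_genus_rejected(self):
        table, meta, _, labels = make_cohort(seed=4, n_samples_per_batch=[40])
        with pytest.raises(ValueError, match="absent from base"):
            cross_cohort_refine(table, meta, labels, ["g__Nowhere"], table,
                                meta, labels)
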