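"""Feature selection and leave-one-subject-out evaluation."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_feature_table
from vrpresence.features import FeatureTable
from vrpresence.recordings import CLASSES
from vrpresence.selection import (
    GaConfig,
    ModelSpec,
    MODEL_FAMILIES,
    compute_metrics,
    fit_predict,
    ga_select,
    loso_cv,
    ovr_auc,
)


def blobs_table(n_subjects=6, epochs_per=8, seed=0, sep=6.0):
    """Well-separated three-class blobs in the registry schema.

    Class centres differ along every feature so that distance-, tree- and
    margin-based families can all separate them."""
    t = random_feature_table(n_subjects, epochs_per, seed)
    rng = np.random.default_rng(seed)
    codes = pd.Categorical(t.y, categories=list(CLASSES)).codes
    d = len(t.feature_names)
    centres = rng.normal(0.0, 1.0, (3, d)) * 0.5 + \
        np.arange(3)[:, None] * sep / np.sqrt(d)
    X = centres[codes] + rng.normal(0.0, 0.05, (len(codes), d))
    t.frame[t.feature_names] = X
    return t


class TestModelSpec:
    def test_printed_hyperparameters_preloaded(self):
        assert ModelSpec("knn").params["n_neighbors"] == 13
        assert ModelSpec("knn").params["leaf_size"] == 1
        assert ModelSpec("mlp").params["hidden_layer_sizes"] == (25,)
        assert ModelSpec("mlp").params["activation"] == "logistic"
        assert ModelSpec("svm").params == {"C": 100.0, "gamma": 0.001,
                                           "kernel": "sigmoid"}
        gbt = ModelSpec("gradient_boosted_trees").params
        assert (gbt["reg_alpha"], gbt["max_depth"], gbt["learning_rate"],
                gbt["n_estimators"]) == (1.0, 7, 0.01, 100)
        rf = ModelSpec("random_forest").params
        assert (rf["max_features"], rf["n_estimators"]) == ("sqrt", 20)
        assert rf["min_leaf_fraction"] == 0.05

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ModelSpec("deep_net")

    def test_rf_min_leaf_resolves_to_5_percent(self):
        pipe = ModelSpec("random_forest").build(n_train_rows=1840)
        assert pipe.named_steps["clf"].min_samples_leaf == 92


class TestFitPredict:
    @pytest.mark.parametrize("family", MODEL_FAMILIES)
    def test_separable_blobs_perfect(self, family):
        t = blobs_table()
        train = t.subset(t.groups != "S01")
        test = t.subset(t.groups == "S01")
        scores, labels = fit_predict(ModelSpec(family), train, test, seed=0)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)
        assert (labels == test.y).mean() == 1.0

    def test_schema_mismatch_rejected(self):
        t = blobs_table()
        other = FeatureTable(t.frame.copy(), list(reversed(t.feature_names)))
        with pytest.raises(ValueError, match="schema"):
            fit_predict(ModelSpec("knn"), t, other)

    def test_missing_training_class_rejected(self):
        t = blobs_table()
        train = t.subset(np.asarray(t.y) != "high")
        with pytest.raises(ValueError, match="absent"):
            fit_predict(ModelSpec("knn"), train, t)

    def test_empty_mask_rejected(self):
        t = blobs_table()
        with pytest.raises(ValueError, match="mask"):
            fit_predict(ModelSpec("knn"), t, t,
                        np.zeros(len(t.feature_names), bool))

    def test_label_permutation_is_chance_level(self):
        t = random_feature_table(6, 20, seed=3)
        perm = t.frame.copy()
        rng = np.random.default_rng(0)
        perm["condition"] = rng.permutation(perm["condition"].to_numpy())
        pt = FeatureTable(perm, t.feature_names)
        train = pt.subset(pt.groups != "S01")
        test = pt.subset(pt.groups == "S01")
        scores, labels = fit_predict(ModelSpec("logistic_regression"),
                                     train, test, seed=0)
        acc = (labels == test.y).mean()
        n = len(test.frame)
        band = 2.576 * np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(acc - 1 / 3) <= band + 0.10  # small-n slack


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array(["low", "medium", "high"] * 4)
        scores = np.zeros((12, 3))
        for i, cls in enumerate(y):
            scores[i, CLASSES.index(cls)] = 1.0
        m = compute_metrics(y, scores)
        assert m["accuracy"] == 1.0
        assert all(v == 1.0 for v in m["f1"].values())
        assert all(v == 1.0 for v in m["auc"].values())

    def test_f1_from_hand_counted_confusion(self):
        # class "high": TP=8, FP=2, FN=4 -> F1 = 16/22 = 0.727
        y = ["high"] * 12 + ["low"] * 10
        pred = (["high"] * 8 + ["low"] * 4) + (["high"] * 2 + ["low"] * 8)
        scores = np.zeros((22, 3))
        for i, cls in enumerate(pred):
            scores[i, CLASSES.index(cls)] = 1.0
        m = compute_metrics(np.array(y), scores)
        assert m["f1"]["high"] == pytest.approx(2 * 8 / (2 * 8 + 2 + 4),
                                                abs=1e-12)

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(1)
        n = 6000
        y = rng.choice(CLASSES, n)
        raw = rng.random((n, 3))
        scores = raw / raw.sum(axis=1, keepdims=True)
        m = compute_metrics(y, scores)
        for cls in CLASSES:
            assert abs(m["auc"][cls] - 0.5) <= 0.05

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 500).astype(bool)
        s = rng.random(500) + 0.3 * y
        assert ovr_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_absent_class_flagged_none(self):
        y = np.array(["low"] * 5 + ["medium"] * 5)
        scores = np.full((10, 3), 1 / 3)
        m = compute_metrics(y, scores)
        assert m["auc"]["high"] is None and m["f1"]["high"] is None


class TestGaSelect:
    def test_informative_feature_recovered_across_seeds(self):
        hits = 0
        for seed in range(10):
            t = random_feature_table(6, 15, seed=seed, informative=42)
            mask = ga_select(
                t, ModelSpec("logistic_regression", {"max_iter": 80}),
                GaConfig(population_size=16, generations=6, rng_seed=seed),
            )
            hits += bool(mask[42])
            assert mask.sum() < 181  # reduces the space on noise tables
        assert hits >= 9

    def test_zero_generations_returns_initial_best(self):
        t = random_feature_table(6, 6, seed=0, informative=3)
        mask = ga_select(t, ModelSpec("logistic_regression", {"max_iter": 50}),
                         GaConfig(population_size=8, generations=0,
                                  rng_seed=1))
        assert mask.any()

    def test_elite_fitness_monotone(self, monkeypatch):
        # track every elite evaluation through a wrapped fitness
        from vrpresence import selection as sel
        seen = []
        orig = sel._inner_cv_accuracy

        def wrapped(spec, table, mask, cfg, seed):
            v = orig(spec, table, mask, cfg, seed)
            seen.append(v)
            return v

        monkeypatch.setattr(sel, "_inner_cv_accuracy", wrapped)
        t = random_feature_table(6, 6, seed=2, informative=7)
        sel.ga_select(t, ModelSpec("logistic_regression", {"max_iter": 50}),
                      GaConfig(population_size=8, generations=4, rng_seed=3))
        running = np.maximum.accumulate(seen)
        assert (np.diff(running) >= 0).all()

    def test_single_class_table_rejected(self):
        t = random_feature_table(4, 4, seed=0)
        sub = t.subset(np.asarray(t.y) == "low")
        with pytest.raises(ValueError, match="single class"):
            ga_select(sub, ModelSpec("knn"), GaConfig(population_size=4,
                                                      generations=1))

    def test_odd_population_rejected(self):
        with pytest.raises(ValueError, match="even"):
            GaConfig(population_size=7)


class TestLosoCv:
    def test_one_fold_per_subject_and_disjointness(self):
        t = blobs_table(n_subjects=5)
        cv = loso_cv(t, ModelSpec("logistic_regression"), seed=0)
        assert cv.n_folds == 5
        assert [f["subject"] for f in cv.folds] == t.subjects

    def test_held_out_fold_artifacts_ignore_test_rows(self):
        # corrupting the held-out subject's rows must not change the mask
        # selected inside that subject's fold
        t = random_feature_table(4, 6, seed=5, informative=11)
        ga = GaConfig(population_size=8, generations=2, rng_seed=0)
        spec = ModelSpec("logistic_regression", {"max_iter": 50})
        cv1 = loso_cv(t, spec, ga_cfg=ga, seed=0)
        corrupted = t.frame.copy()
        rows = corrupted["subject"] == "S01"
        rng = np.random.default_rng(99)
        corrupted.loc[rows, t.feature_names] = rng.standard_normal(
            (int(rows.sum()), len(t.feature_names)))
        cv2 = loso_cv(FeatureTable(corrupted, t.feature_names), spec,
                      ga_cfg=ga, seed=0)
        np.testing.assert_array_equal(cv1.folds[0]["mask"],
                                      cv2.folds[0]["mask"])

    def test_single_class_subject_flagged_not_dropped(self):
        t = blobs_table(n_subjects=4)
        frame = t.frame[~((t.frame["subject"] == "S01")
                          & (t.frame["condition"] != "low"))].reset_index(
            drop=True)
        cv = loso_cv(FeatureTable(frame, t.feature_names),
                     ModelSpec("logistic_regression"), seed=0)
        flags = {f["subject"]: f["flag"] for f in cv.folds}
        assert flags["S01"] is not None
        assert cv.n_folds == 4

    def test_too_few_subjects_rejected(self):
        t = blobs_table(n_subjects=2)
        with pytest.raises(ValueError, match="3 subjects"):
            loso_cv(t, ModelSpec("knn"))
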