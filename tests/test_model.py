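import numpy as np
import pandas as pd
import pytest

from nanocorona.model import (
    ClassifierConfig,
    SmoteConfig,
    cross_biofluid_validate,
    grid_search,
    load_model,
    predict_corona,
    save_model,
    smote,
    train,
    validate,
)

FAST_CFG = ClassifierConfig(n_trees=50)
FAST_SMOTE = SmoteConfig(k_neighbors=3)


def separable_data(n=60, seed=0):
    """Two feature clusters fully separated along the first axis."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(n, 4))
    y = np.zeros(n, dtype=bool)
    y[: n // 3] = True  # imbalanced positive minority
    X[:, 0] = np.where(y, 0.8, 0.2) + rng.uniform(-0.1, 0.1, size=n)
    return pd.DataFrame(X, columns=list("abcd")), y


class TestSmote:
    def test_no_synthesis_when_ratio_met(self):
        minority = np.random.default_rng(0).uniform(size=(50, 3))
        out = smote(minority, n_majority=60, cfg=SmoteConfig(k_neighbors=5))
        assert out.shape == (0, 3)

    def test_target_count(self):
        minority = np.random.default_rng(0).uniform(size=(20, 3))
        out = smote(minority, n_majority=100,
                    cfg=SmoteConfig(ratio=0.7, k_neighbors=5, seed=0))
        assert out.shape[0] == 70 - 20

    def test_identical_points_synthesize_the_same_point(self):
        minority = np.ones((5, 2))
        out = smote(minority, n_majority=20,
                    cfg=SmoteConfig(k_neighbors=1, seed=0))
        assert np.allclose(out, 1.0)

    def test_segment_geometry_two_points(self):
        minority = np.array([[0.0, 0.0], [1.0, 1.0]])
        out = smote(minority, n_majority=20,
                    cfg=SmoteConfig(k_neighbors=1, seed=0))
        # every point lies on the segment: both coordinates equal, in [0,1]
        assert np.allclose(out[:, 0], out[:, 1])
        assert (out >= 0).all() and (out <= 1).all()

    def test_k_must_be_below_minority_size(self):
        with pytest.raises(ValueError, match="smaller k"):
            smote(np.ones((3, 2)), 10, SmoteConfig(k_neighbors=5))

    def test_deterministic_given_seed(self):
        minority = np.random.default_rng(1).uniform(size=(15, 4))
        cfg = SmoteConfig(k_neighbors=4, seed=9)
        assert np.array_equal(
            smote(minority, 50, cfg), smote(minority, 50, cfg)
        )

    def test_synthetic_points_in_minority_convex_hull_boxwise(self):
        rng = np.random.default_rng(2)
        minority = rng.uniform(0.3, 0.6, size=(30, 5))
        out = smote(minority, 100, SmoteConfig(k_neighbors=5, seed=1))
        assert (out >= minority.min(0) - 1e-12).all()
        assert (out <= minority.max(0) + 1e-12).all()


class TestTrain:
    def test_separable_training_accuracy(self):
        X, y = separable_data()
        model = train(X, y, FAST_CFG, FAST_SMOTE)
        pred = predict_corona(model, X)
        assert (pred["in_corona"].to_numpy() == y).mean() == 1.0

    def test_deterministic_given_seeds(self):
        X, y = separable_data()
        cfg = ClassifierConfig(n_trees=30, seed=5)
        scfg = SmoteConfig(k_neighbors=3, seed=5)
        p1 = predict_corona(train(X, y, cfg, scfg), X)
        p2 = predict_corona(train(X, y, cfg, scfg), X)
        pd.testing.assert_frame_equal(p1, p2)

    def test_single_class_rejected(self):
        X, _ = separable_data()
        with pytest.raises(ValueError, match="single class"):
            train(X, np.ones(len(X), dtype=bool), FAST_CFG, FAST_SMOTE)

    def test_empty_feature_set_rejected(self):
        X, y = separable_data()
        with pytest.raises(ValueError, match="empty"):
            train(X[[]], y, FAST_CFG, FAST_SMOTE)


class TestPredict:
    def test_probability_cutoff_inclusive_at_half(self):
        X, y = separable_data()
        model = train(X, y, ClassifierConfig(n_trees=2, seed=0), FAST_SMOTE)
        pred = predict_corona(model, X)
        at_half = pred["probability"] == 0.5
        if at_half.any():
            assert pred.loc[at_half, "in_corona"].all()
        assert (pred["in_corona"] == (pred["probability"] >= 0.5)).all()

    def test_registry_mismatch_listed(self):
        X, y = separable_data()
        model = train(X, y, FAST_CFG, FAST_SMOTE)
        bad = X.rename(columns={"a": "z"})
        with pytest.raises(ValueError) as err:
            predict_corona(model, bad)
        assert "a" in str(err.value) and "z" in str(err.value)

    def test_round_trip_persistence(self, tmp_path):
        X, y = separable_data()
        model = train(X, y, ClassifierConfig(n_trees=20, seed=1), FAST_SMOTE)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        pd.testing.assert_frame_equal(
            predict_corona(model, X), predict_corona(loaded, X)
        )
        assert path.with_suffix(".joblib.json").exists()


class TestValidate:
    def test_separable_scores_high(self):
        X, y = separable_data(n=90)
        res = validate(X, y, n_splits=20, cfg=FAST_CFG,
                       smote_cfg=FAST_SMOTE, seed=0)
        assert res.mean("accuracy") >= 0.95
        assert res.mean("auc") >= 0.95

    def test_permuted_labels_score_at_chance(self):
        # n and feature count sized so the dataset-level null bias of the
        # mean rank statistic stays well inside the chance band
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            rng.uniform(size=(400, 20)),
            columns=[f"f{i}" for i in range(20)],
        )
        y = rng.random(400) < 0.4
        res = validate(X, y, n_splits=60, cfg=FAST_CFG,
                       smote_cfg=FAST_SMOTE, seed=1)
        assert 0.45 <= res.mean("auc") <= 0.55

    def test_single_split_ci_degenerate(self):
        X, y = separable_data()
        res = validate(X, y, n_splits=1, cfg=FAST_CFG,
                       smote_cfg=FAST_SMOTE, seed=0)
        lo, hi = res.ci95("accuracy")
        assert lo == hi == res.mean("accuracy")

    def test_per_split_lists_have_n_splits_entries(self):
        X, y = separable_data()
        res = validate(X, y, n_splits=7, cfg=FAST_CFG,
                       smote_cfg=FAST_SMOTE, seed=0)
        assert all(len(v) == 7 for v in res.metrics.values())

    def test_leakage_mode_recall_not_below_leakfree(self):
        # oversampling before the split leaks synthetic copies of test
        # information into training; recall must not be hurt by it
        X, y = separable_data(n=90, seed=4)
        noise = np.random.default_rng(4).uniform(size=(90, 4))
        X = pd.DataFrame(0.35 * X.to_numpy() + 0.65 * noise,
                         columns=X.columns)
        kwargs = dict(n_splits=20, cfg=FAST_CFG, smote_cfg=FAST_SMOTE,
                      seed=2)
        clean = validate(X, y, **kwargs)
        leaky = validate(X, y, smote_before_split=True, **kwargs)
        assert leaky.mean("recall") >= clean.mean("recall") - 1e-9


class TestCrossBiofluid:
    def test_fraction_scaling(self):
        X_a, y_a = separable_data(n=62, seed=1)
        X_b, y_b = separable_data(n=112, seed=2)
        res = cross_biofluid_validate(
            X_a, y_a, X_b, y_b, n_total=174, n_repeats=5,
            cfg=FAST_CFG, smote_cfg=FAST_SMOTE, seed=0,
        )
        assert res.test_fraction == pytest.approx(0.1 * 174 / 112)

    def test_equal_sets_give_plain_fraction(self):
        X_a, y_a = separable_data(n=100, seed=1)
        res = cross_biofluid_validate(
            X_a, y_a, X_a, y_a, n_total=100, n_repeats=3,
            cfg=FAST_CFG, smote_cfg=FAST_SMOTE, seed=0,
        )
        assert res.test_fraction == pytest.approx(0.1)

    def test_overlarge_fraction_capped(self):
        X_a, y_a = separable_data(n=100, seed=1)
        X_b, y_b = separable_data(n=30, seed=2)
        res = cross_biofluid_validate(
            X_a, y_a, X_b, y_b, n_total=1000, n_repeats=3,
            cfg=FAST_CFG, smote_cfg=FAST_SMOTE, seed=0,
        )
        assert res.test_fraction == 1.0


class TestGridSearch:
    def test_singleton_grid_returned(self):
        X, y = separable_data()
        cfg = ClassifierConfig(n_trees=25)
        best, table = grid_search(X, y, [cfg], n_splits=3,
                                  smote_cfg=FAST_SMOTE, seed=0)
        assert best == cfg
        assert len(table) == 1

    def test_score_table_emitted_for_full_grid(self):
        X, y = separable_data()
        grid = [ClassifierConfig(n_trees=5), ClassifierConfig(n_trees=25)]
        best, table = grid_search(X, y, grid, n_splits=3,
                                  smote_cfg=FAST_SMOTE, seed=0)
        assert best in grid
        assert set(table["n_trees"]) == {5, 25}
        assert {"accuracy", "auc", "precision", "recall"} <= set(table)

    def test_unknown_objective_rejected(self):
        X, y = separable_data()
        with pytest.raises(ValueError, match="objective"):
            grid_search(X, y, [FAST_CFG], objective="f1", n_splits=2)
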