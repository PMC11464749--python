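import numpy as np
import pytest

from qsprkit import TrainingConfig, ValidationError, cross_validate, make_model, optimize
from qsprkit.errors import ContractError
from qsprkit.modeling import (
    HYPERPARAMETER_SPACES,
    default_point,
    derive_seed,
    get_space,
    split_train_test,
    train_final,
)


def linear_data(n=100, p=5, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    w = rng.normal(size=p)
    y = X @ w + noise * rng.normal(size=n)
    return X, y


class TestMakeModel:
    @pytest.mark.parametrize("family", sorted(HYPERPARAMETER_SPACES))
    @pytest.mark.parametrize("task", ["regression", "classification"])
    def test_registry_covers_both_tasks(self, family, task):
        model = make_model(family, default_point(family, task), seed=0, task=task)
        assert hasattr(model, "fit") and hasattr(model, "predict")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValidationError):
            make_model("cnn", {}, seed=0)

    def test_out_of_domain_point_rejected(self):
        with pytest.raises(ValidationError):
            make_model("ridge", {"alpha": -1.0}, seed=0)

    def test_ridge_recovers_noiseless_linear_map(self):
        X, y = linear_data()
        m = make_model("ridge", {"alpha": 1e-4}, seed=0)
        m.fit(X, y)
        assert np.mean((m.predict(X) - y) ** 2) < 1e-6

    def test_xgboost_seeded_determinism(self):
        X, y = linear_data(noise=0.1, seed=1)
        preds = []
        for _ in range(2):
            m = make_model("xgboost", default_point("xgboost", "regression"),
                           seed=5, task="regression")
            m.fit(X, y)
            preds.append(m.predict(X))
        assert np.array_equal(preds[0], preds[1])


class TestCrossValidate:
    def test_folds_partition_all_rows(self):
        # Verified indirectly: 100 rows, 5 folds -> 5 objectives, each fold
        # of 20 (ridge on noiseless data makes every fold near-exact).
        X, y = linear_data(n=100)
        obj = cross_validate(lambda s: make_model("ridge", {"alpha": 1e-4}, s),
                             X, y, 5, "regression", seed=0)
        assert obj.shape == (5,)
        assert np.all(obj < 1e-6)

    def test_stratified_folds_balanced_within_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 3))
        y = np.array([1] * 24 + [0] * 36)
        from qsprkit.modeling import _folds

        global_frac = y.mean()
        for tr, va in _folds(y, 5, "classification", seed=1):
            assert abs(y[va].sum() - global_frac * len(va)) <= 1.0

    def test_small_class_suggests_fewer_folds(self):
        X = np.zeros((10, 2))
        y = np.array([1, 1, 1] + [0] * 7)
        with pytest.raises(ValidationError, match="folds"):
            cross_validate(lambda s: make_model("ridge", {"alpha": 1.0}, s, "classification"),
                           X, y, 5, "classification", seed=0)

    def test_perfect_classifier_gives_zero_objective(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(-5, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        obj = cross_validate(
            lambda s: make_model("ridge", {"alpha": 1e-2}, s, "classification"),
            X, y, 4, "classification", seed=0)
        assert np.all(obj == 0.0)

    def test_preprocess_refit_per_fold(self):
        calls = []
        X, y = linear_data(n=30)

        def preprocess(tr, va):
            calls.append((len(tr), len(va)))
            return X[tr], X[va]

        cross_validate(lambda s: make_model("ridge", {"alpha": 1e-3}, s),
                       None, y, 3, "regression", seed=0, preprocess=preprocess)
        assert len(calls) == 3
        assert all(t + v == 30 for t, v in calls)


class TestOptimize:
    def test_budget_exactness_and_running_minimum(self):
        X, y = linear_data(n=60, noise=0.2, seed=3)
        for strategy in ("tpe", "random"):
            cfg = TrainingConfig(model_family="ridge", hpo_max_evals=17,
                                 cv_folds=3, seed=1)
            best, trials = optimize(get_space("ridge", "regression"), X, y,
                                    cfg, strategy=strategy)
            assert len(trials) == 17
            means = [t.mean_objective for t in trials]
            running = np.minimum.accumulate(means)
            assert np.all(np.diff(running) <= 0)
            assert min(means) == pytest.approx(
                next(t.mean_objective for t in trials
                     if t.hyperparameters == best))

    def test_trial_records_consistent(self):
        X, y = linear_data(n=40, noise=0.1, seed=4)
        cfg = TrainingConfig(model_family="ridge", hpo_max_evals=5,
                             cv_folds=4, seed=2)
        _, trials = optimize(get_space("ridge", "regression"), X, y, cfg)
        for t in trials:
            assert len(t.fold_objectives) == 4
            assert t.mean_objective == pytest.approx(np.mean(t.fold_objectives))

    def test_all_trials_failing_raises_first_failure(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        cfg = TrainingConfig(model_family="ridge", hpo_max_evals=3,
                             cv_folds=2, seed=0)

        def broken(tr, va):
            raise RuntimeError("boom")

        with pytest.raises(ContractError, match="boom"):
            optimize(get_space("ridge", "regression"), None, y, cfg,
                     preprocess=broken)


class TestTrainFinalAndSplit:
    def test_final_fit_is_exact_on_noiseless_data(self):
        X, y = linear_data(n=80)
        names = [f"f{i}" for i in range(X.shape[1])]
        m = train_final("ridge", {"alpha": 1e-4}, X, y, seed=0, feature_names=names)
        assert np.mean((m.predict(X, names) - y) ** 2) < 1e-6

    def test_same_seed_identical_predictions(self):
        X, y = linear_data(n=50, noise=0.3, seed=6)
        names = [f"f{i}" for i in range(X.shape[1])]
        point = default_point("random_forest", "regression")
        a = train_final("random_forest", point, X, y, 9, names)
        b = train_final("random_forest", point, X, y, 9, names)
        assert np.array_equal(a.predict(X, names), b.predict(X, names))

    def test_feature_name_mismatch_is_contract_error(self):
        X, y = linear_data(n=20)
        names = [f"f{i}" for i in range(X.shape[1])]
        m = train_final("ridge", {"alpha": 1.0}, X, y, 0, names)
        with pytest.raises(ContractError, match="feature-name"):
            m.predict(X, list(reversed(names)))

    def test_split_fraction_and_stratification(self):
        y = np.array([1] * 30 + [0] * 70)
        tr, te = split_train_test(y, 0.1, seed=0, task="classification")
        assert len(te) == 10 and len(tr) == 90
        assert set(tr) | set(te) == set(range(100))
        assert y[te].sum() == 3  # stratified 30% positives

    def test_derived_seeds_stable_and_distinct(self):
        assert derive_seed(7, "split") == derive_seed(7, "split")
        assert derive_seed(7, "split") != derive_seed(7, "hpo")
        assert 0 <= derive_seed(7, "split") < 2**31
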