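import numpy as np
import pandas as pd
import pytest

import proxistate as px
from proxistate.regression import (ProximityRegression, RidgeModel,
                                   baseline_rmse, fit_ridge, make_splits,
                                   pair_membership, rmse)


def _toy_dataset(n_frags=16, n_feat=4, seed=0, betas=None, noise=0.1):
    """Pairs over a 2-chromosome toy genome with a linear planted target."""
    rng = np.random.default_rng(seed)
    half = n_frags // 2
    idx_i, idx_j = [], []
    for i in range(half):
        for j in range(half, n_frags):
            idx_i.append(i)
            idx_j.append(j)
    idx_i, idx_j = np.array(idx_i), np.array(idx_j)
    X = rng.normal(0, 1, (len(idx_i), n_feat))
    betas = np.zeros(n_feat) if betas is None else np.asarray(betas)
    y = X @ betas + rng.normal(0, noise, len(idx_i))
    names = [f"f{k}" for k in range(n_feat)]
    return ProximityRegression(X, y, idx_i, idx_j, names, alpha_policy=1e-6)


class TestSplits:
    def test_four_fragments_halved(self):
        splits = make_splits(np.arange(4), n_splits=3, seed=0)
        for s in splits:
            assert len(s.train_fragments) == len(s.test_fragments) == 2
            assert set(s.train_fragments) | set(s.test_fragments) == set(range(4))

    def test_same_seed_identical(self):
        a = make_splits(np.arange(10), 5, seed=7)
        b = make_splits(np.arange(10), 5, seed=7)
        for s, t in zip(a, b):
            assert (s.train_fragments == t.train_fragments).all()

    def test_odd_count_allowed(self):
        s = make_splits(np.arange(7), 1, seed=0)[0]
        assert {len(s.train_fragments), len(s.test_fragments)} == {3, 4}

    def test_rows_partition_into_train_test_discarded(self):
        model = _toy_dataset()
        split = make_splits(model.fragments, 1, seed=1)[0]
        train = pair_membership(model.idx_i, model.idx_j,
                                split.train_fragments)
        test = pair_membership(model.idx_i, model.idx_j,
                               split.test_fragments)
        assert not (train & test).any()
        # every row is train, test, or crosses the halves
        crossing = ~(train | test)
        assert train.sum() + test.sum() + crossing.sum() == len(model.y)
        assert crossing.sum() > 0

    def test_too_few_fragments(self):
        with pytest.raises(ValueError):
            make_splits(np.arange(3), 1, seed=0)


class TestRidge:
    def test_near_zero_penalty_recovers_slope(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (200, 1))
        y = 2.0 * X[:, 0]
        model = fit_ridge(X, y, alpha_policy=1e-9)
        assert model.destandardized_coef_[0] == pytest.approx(2.0, abs=1e-6)

    def test_infinite_penalty_predicts_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (100, 2))
        y = rng.normal(5, 1, 100)
        model = fit_ridge(X, y, alpha_policy=1e12)
        assert np.allclose(model.predict(X), y.mean(), atol=1e-6)

    def test_constant_feature_zero_coefficient(self):
        X = np.column_stack([np.ones(50), np.arange(50.0)])
        y = np.arange(50.0)
        model = fit_ridge(X, y, alpha_policy=1e-6)
        assert model.coef_[0] == 0.0

    def test_empty_feature_set_is_baseline(self):
        y = np.array([1.0, 2.0, 3.0])
        model = RidgeModel(1.0).fit(np.empty((3, 0)), y)
        assert np.allclose(model.predict(np.empty((2, 0))), 2.0)

    def test_cv_policy_runs(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (80, 3))
        y = X[:, 0] + rng.normal(0, 0.1, 80)
        model = fit_ridge(X, y, alpha_policy="cv")
        assert model.alpha > 0


class TestEvaluate:
    def test_two_rmse_values_per_split(self):
        model = _toy_dataset(betas=[1, 0, 0, 0])
        splits = make_splits(model.fragments, 10, seed=0)
        res = model.evaluate(["f0"], splits)
        assert res.n_values == 20

    def test_planted_linear_beats_baseline_significantly(self):
        model = _toy_dataset(betas=[2, 0, 0, 0], noise=0.05)
        splits = make_splits(model.fragments, 20, seed=1)
        res = model.evaluate(["f0"], splits)
        assert res.mean_rmse < 0.1 < res.mean_baseline
        assert res.p_value < 1e-6

    def test_zero_feature_model_identical_to_baseline(self):
        model = _toy_dataset(betas=[1, 0, 0, 0])
        splits = make_splits(model.fragments, 5, seed=2)
        res = model.evaluate([], splits)
        assert np.allclose(res.model_rmse, res.baseline_rmse)
        assert res.p_value == 1.0

    def test_baseline_closed_form(self):
        model = _toy_dataset(betas=[1, 1, 0, 0], seed=3)
        split = make_splits(model.fragments, 1, seed=3)[0]
        tr, te = model._split_rows(split)
        res = model.evaluate([], [split])
        expected = np.sqrt(np.mean(
            (model.y[te] - model.y[tr].mean()) ** 2))
        assert res.baseline_rmse[0] == pytest.approx(expected)

    def test_pure_noise_feature_not_significant(self):
        wins = 0
        for seed in range(10):
            model = _toy_dataset(betas=[0, 0, 0, 0], noise=1.0, seed=seed)
            splits = make_splits(model.fragments, 10, seed=seed)
            res = model.evaluate(["f0"], splits)
            if res.p_value < 0.05 and res.mean_rmse < res.mean_baseline:
                wins += 1
        assert wins <= 2


class TestSelection:
    def test_dominant_feature_ranked_first(self):
        for seed in range(5):
            model = _toy_dataset(betas=[0, 3, 0, 0], noise=0.2, seed=seed)
            splits = make_splits(model.fragments, 4, seed=seed)
            sel = model.successive_selection(splits, seed=seed)
            assert sel.order[0] == "f1"
            assert len(sel.curve) == 4

    def test_single_feature_trivial_order(self):
        model = _toy_dataset(n_feat=1, betas=[1.0], seed=0)
        splits = make_splits(model.fragments, 2, seed=0)
        sel = model.successive_selection(splits)
        assert sel.order == ["f0"]

    def test_curve_improves_for_nested_informative_features(self):
        model = _toy_dataset(betas=[1.5, 1.0, 0, 0], noise=0.1, seed=4)
        splits = make_splits(model.fragments, 6, seed=4)
        sel = model.successive_selection(splits, seed=4)
        curve = sel.curve["rmse_mean"].to_numpy()
        assert curve[1] <= curve[0] + 0.02

    def test_greedy_skips_redundant_copy(self):
        rng = np.random.default_rng(6)
        model = _toy_dataset(betas=[2, 0, 0, 0], noise=0.2, seed=6)
        X = model.X.copy()
        X[:, 1] = X[:, 0]  # exact duplicate of the planted feature
        model = ProximityRegression(X, model.y, model.idx_i, model.idx_j,
                                    model.feature_names, alpha_policy=1e-6)
        splits = make_splits(model.fragments, 4, seed=6)
        sel = model.greedy_selection(splits, seed=6, stability_splits=0)
        first_two = set(sel.order[:2])
        assert "f0" in first_two or "f1" in first_two
        # the duplicate adds nothing once its twin is in
        curve = sel.curve["rmse_mean"].to_numpy()
        assert abs(curve[1] - curve[0]) < 0.05

    def test_greedy_stability_of_planted_pair(self):
        model = _toy_dataset(n_frags=24, betas=[2, -1.5, 0, 0], noise=0.05,
                             seed=7)
        splits = make_splits(model.fragments, 6, seed=7)
        sel = model.greedy_selection(splits, seed=7, max_features=3)
        stable = sel.stable_features(2, threshold=0.9)
        assert set(stable) == {"f0", "f1"}

    def test_selection_ignores_test_targets(self):
        """Greedy ordering computed from a split's training rows is
        unchanged when the corresponding test targets are scrambled."""
        model = _toy_dataset(betas=[1, 0.5, 0, 0], noise=0.2, seed=8)
        split = make_splits(model.fragments, 1, seed=8)[0]
        tr, te = model._split_rows(split)
        rng = np.random.default_rng(0)
        order1 = model._greedy_order(tr, np.random.default_rng(1), 5, 1.0)
        y2 = model.y.copy()
        y2[te] = rng.permutation(y2[te])
        scrambled = ProximityRegression(model.X, y2, model.idx_i,
                                        model.idx_j, model.feature_names)
        order2 = scrambled._greedy_order(tr, np.random.default_rng(1), 5, 1.0)
        assert order1 == order2


class TestResultsObject:
    def test_fit_returns_summary_and_params(self, pair_table):
        model = ProximityRegression.from_pair_table(
            pair_table, features=["D_expression", "A_expression", "D_DNAse"],
            alpha_policy=1.0)
        results = model.fit(n_splits=5, seed=0)
        assert set(results.params.index) == {"D_expression", "A_expression",
                                             "D_DNAse"}
        text = results.summary()
        assert "baseline RMSE" in text and "D_expression" in text
        assert results.evaluation.n_values == 10

    def test_planted_feature_recovery_from_pair_table(self, pair_table):
        """Selection recovers a proximity signal planted as a linear
        function of two named features, with matching signs."""
        planted = px.plant_linear_proximity(
            pair_table, {"A_DNAse": 1.5, "D_DNAse": -2.5},
            noise_sd=0.5, seed=11)
        feats = ["A_DNAse", "D_DNAse", "A_expression", "D_expression",
                 "A_methylation", "D_methylation"]
        model = ProximityRegression.from_pair_table(
            planted, features=feats, alpha_policy=1.0)
        splits = make_splits(model.fragments, 4, seed=11)
        sel = model.successive_selection(splits, seed=11)
        assert set(sel.order[:2]) == {"A_DNAse", "D_DNAse"}
        results = model.fit(features=feats, splits=splits)
        assert results.params["A_DNAse"] > 0
        assert results.params["D_DNAse"] < 0
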