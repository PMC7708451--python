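"""Model contracts: splits, evaluation statistics, small-scale training."""

import numpy as np
import pandas as pd
import pytest

from reggrammar import models as mdl


class TestSplitPlan:
    def test_disjoint_and_exhaustive(self):
        ids = [f"g{i}" for i in range(100)]
        plan = mdl.SplitPlan.make(ids, seed=1)
        all_ids = plan.train + plan.validation + plan.test
        assert sorted(all_ids) == sorted(ids)
        assert len(set(plan.train) & set(plan.test)) == 0
        assert len(plan.train) == 80

    def test_same_seed_same_split(self):
        ids = [f"g{i}" for i in range(57)]
        a = mdl.SplitPlan.make(ids, seed=9)
        b = mdl.SplitPlan.make(ids, seed=9)
        assert a.train == b.train and a.test == b.test

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            mdl.SplitPlan.make(["a", "b"], fractions=(0.5, 0.2, 0.2))


class TestEvaluate:
    def test_perfect_prediction(self):
        rep = mdl.evaluate([1, 2, 3], [1, 2, 3])
        assert rep.r_squared == 1.0 and rep.mse == 0.0

    def test_mean_predictor_zero(self):
        rep = mdl.evaluate([2, 2, 2], [1, 2, 3])
        assert rep.r_squared == 0.0

    def test_negative_r_squared_hand_computation(self):
        # SS_res = 4 + 0 + 4 = 8, SS_tot = 2 -> R2 = 1 - 8/2 = -3
        rep = mdl.evaluate([3, 2, 1], [1, 2, 3])
        assert rep.r_squared == pytest.approx(-3.0)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            pred, obs = rng.normal(size=20), rng.normal(size=20)
            rep = mdl.evaluate(pred, obs)
            expect = 1 - np.sum((obs - pred) ** 2) / np.sum((obs - obs.mean()) ** 2)
            assert rep.r_squared == pytest.approx(expect, abs=1e-12)

    def test_f_test_significance_direction(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        good = mdl.evaluate(x + rng.normal(0, 0.1, 50), x)
        null = mdl.evaluate(rng.normal(size=50), x)
        assert good.f_pvalue < 1e-10
        assert null.f_pvalue > 1e-4

    def test_zero_ss_total_rejected(self):
        with pytest.raises(ValueError):
            mdl.evaluate([1, 2, 3], [5, 5, 5])


class TestBuildModel:
    def test_forward_smoke_finite_scalars(self):
        spec = mdl.ModelSpec(conv_blocks=[mdl.ConvBlock(8, 6, 4, 0.0),
                                          mdl.ConvBlock(8, 4, 4, 0.0),
                                          mdl.ConvBlock(8, 3, 2, 0.0)],
                             fc_layers=(16, 8))
        m = mdl.build_model(spec, (4, 200), 72)
        rng = np.random.default_rng(0)
        out = m.predict(rng.random((2, 4, 200)), rng.random((2, 72)))
        assert out.shape == (2,) and np.isfinite(out).all()

    def test_deterministic_inference(self):
        spec = mdl.ModelSpec(conv_blocks=[mdl.ConvBlock(4, 5, -1, 0.0)],
                             fc_layers=(8,), fc_dropout=0.0, batchnorm=False)
        m = mdl.build_model(spec, (4, 60), 3)
        rng = np.random.default_rng(1)
        xs, xn = rng.random((3, 4, 60)), rng.random((3, 3))
        np.testing.assert_array_equal(m.predict(xs, xn), m.predict(xs, xn))

    def test_zero_filter_spec_rejected(self):
        spec = mdl.ModelSpec(conv_blocks=[mdl.ConvBlock(0, 5, 2, 0.0)])
        with pytest.raises(ValueError):
            mdl.build_model(spec, (4, 100), 10)

    def test_three_conv_two_fc_by_default(self):
        spec = mdl.ModelSpec()
        assert len(spec.conv_blocks) == 3
        assert len(spec.fc_layers) == 2


class TestTraining:
    def _toy(self, n=300, L=60, seed=0):
        rng = np.random.default_rng(seed)
        xs = np.zeros((n, 4, L), dtype=np.float32)
        xs[np.arange(n)[:, None], rng.integers(0, 4, (n, L)),
           np.arange(L)[None, :]] = 1
        xn = rng.normal(size=(n, 5))
        ids = [f"g{i}" for i in range(n)]
        return xs, xn, ids

    def test_constant_targets_converge(self):
        xs, xn, ids = self._toy()
        split = mdl.SplitPlan.make(ids, seed=0)
        spec = mdl.ModelSpec(conv_blocks=[mdl.ConvBlock(4, 5, -1, 0.0)],
                             fc_layers=(8,), fc_dropout=0.0, batchnorm=False,
                             epochs=50, patience=50, learning_rate=1e-2, seed=1)
        m = mdl.build_model(spec, (4, 60), 5)
        m, hist = mdl.train(m, xs, xn, np.zeros(len(ids)), split, ids)
        assert hist["val_mse"].min() <= 1e-3

    def test_checkpoint_is_validation_minimum(self):
        xs, xn, ids = self._toy()
        rng = np.random.default_rng(2)
        y = xn[:, 0] + 0.1 * rng.normal(size=len(ids))
        split = mdl.SplitPlan.make(ids, seed=0)
        spec = mdl.ModelSpec(conv_blocks=[mdl.ConvBlock(4, 5, -1, 0.0)],
                             fc_layers=(8,), fc_dropout=0.0, batchnorm=False,
                             epochs=30, patience=30, seed=1)
        m = mdl.build_model(spec, (4, 60), 5)
        m, hist = mdl.train(m, xs, xn, y, split, ids)
        idx = split.indices(ids)
        val_mse = float(np.mean(
            (m.predict(xs[idx["validation"]], xn[idx["validation"]])
             - y[idx["validation"]]) ** 2))
        assert val_mse <= hist["val_mse"].min() + 1e-6

    def test_numeric_feature_signal_learned(self):
        xs, xn, ids = self._toy(seed=3)
        y = 2.0 * xn[:, 1] - xn[:, 3]
        split = mdl.SplitPlan.make(ids, seed=0)
        spec = mdl.ModelSpec(conv_blocks=[mdl.ConvBlock(4, 5, -1, 0.0)],
                             fc_layers=(16,), fc_dropout=0.0, batchnorm=False,
                             epochs=60, patience=60, seed=1)
        m = mdl.build_model(spec, (4, 60), 5)
        m, _ = mdl.train(m, xs, xn, y, split, ids)
        idx = split.indices(ids)
        rep = mdl.evaluate(m.predict(xs[idx["test"]], xn[idx["test"]]),
                           y[idx["test"]])
        assert rep.r_squared > 0.8


class TestShallowBaseline:
    def test_exact_linear_function_of_one_kmer(self):
        rng = np.random.default_rng(0)
        n = 120
        feats = pd.DataFrame(
            rng.integers(0, 10, size=(n, 6)).astype(float),
            index=[f"g{i}" for i in range(n)],
            columns=[f"promoter:KMER{j}" for j in range(6)],
        )
        y = 3.0 * feats.iloc[:, 2].to_numpy() - 1.0
        split = mdl.SplitPlan.make(list(feats.index), seed=0)
        rep, info = mdl.shallow_baseline(feats, y, "linear", split)
        assert rep.r_squared >= 0.999

    def test_singular_design_falls_back_to_ridge(self):
        rng = np.random.default_rng(1)
        n = 60
        base = rng.normal(size=(n, 3))
        X = np.concatenate([base, base[:, :1] * 2], axis=1)  # collinear
        feats = pd.DataFrame(X, index=[f"g{i}" for i in range(n)])
        y = base[:, 0]
        split = mdl.SplitPlan.make(list(feats.index), seed=0)
        with pytest.warns(UserWarning, match="ridge"):
            rep, info = mdl.shallow_baseline(feats, y, "linear", split)
        assert info["algorithm"] == "ridge"

    @pytest.mark.parametrize("algorithm", ["ridge", "lasso", "elastic-net",
                                           "random-forest", "svm", "knn"])
    def test_algorithms_run_and_beat_null(self, algorithm):
        rng = np.random.default_rng(2)
        n = 150
        X = rng.normal(size=(n, 8))
        y = X[:, 0] + 0.5 * X[:, 1] + 0.1 * rng.normal(size=n)
        feats = pd.DataFrame(X, index=[f"g{i}" for i in range(n)])
        split = mdl.SplitPlan.make(list(feats.index), seed=0)
        rep, _ = mdl.shallow_baseline(feats, y, algorithm, split)
        assert rep.r_squared > 0.3


class TestRandomSearch:
    def test_returns_best_spec_by_validation_mse(self):
        rng = np.random.default_rng(0)
        n, L = 150, 400  # the sampled conv stacks expect a few hundred bp
        xs = np.zeros((n, 4, L), dtype=np.float32)
        xs[np.arange(n)[:, None], rng.integers(0, 4, (n, L)),
           np.arange(L)[None, :]] = 1
        xn = rng.normal(size=(n, 3))
        y = xn[:, 0]
        ids = [f"g{i}" for i in range(n)]
        split = mdl.SplitPlan.make(ids, seed=0)
        spec, trace = mdl.random_search(xs, xn, y, split, ids,
                                        n_iter=2, seed=1, epochs=2)
        assert isinstance(spec, mdl.ModelSpec)
        assert len(trace) == 2
        assert trace["val_mse"].min() >= 0


class TestPooledR2:
    def test_average_profile_predictor_scores_zero(self):
        rng = np.random.default_rng(0)
        obs = rng.dirichlet(np.ones(8), size=40)
        pred = np.tile(obs.mean(axis=0), (40, 1))
        assert mdl.pooled_r2(pred, obs) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_prediction_scores_one(self):
        rng = np.random.default_rng(1)
        obs = rng.dirichlet(np.ones(8), size=10)
        assert mdl.pooled_r2(obs.copy(), obs) == 1.0
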