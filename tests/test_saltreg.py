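
import numpy as np
import pytest

from ramansalt.errors import FitError, InputError, ParameterError
from ramansalt.saltreg import (
    KERNEL_TAGS,
    EvalReport,
    GPRFactory,
    RegressionTreeModel,
    RidgeLinearModel,
    RQKernelParams,
    SplitSpec,
    cross_validate,
    evaluate,
    fit_baselines,
    fit_gpr,
    kernel_matrix,
    leave_one_concentration_out,
    predict_gpr,
    predict_week,
    rq_kernel,
    stratified_split,
)


class TestRQKernel:
    def test_zero_distance_is_signal_variance(self):
        p = RQKernelParams(length_scale=1.0, alpha=1.0, signal_sd=1.0)
        assert rq_kernel(np.array([1.0, 2.0]), np.array([1.0, 2.0]), p) == 1.0

    def test_direct_substitution(self):
        # r = sqrt(2), l = 1, alpha = 1 -> (1 + 2/2)^(-1) = 0.5
        p = RQKernelParams(length_scale=1.0, alpha=1.0, signal_sd=1.0)
        assert rq_kernel(np.array([0.0, 0.0]), np.array([1.0, 1.0]), p) == pytest.approx(0.5)

    @pytest.mark.parametrize("r", [0.0, 0.5, 1.0, 2.0, 5.0])
    def test_large_alpha_limit_is_squared_exponential(self, r):
        p = RQKernelParams(length_scale=1.0, alpha=1e8, signal_sd=1.0)
        val = rq_kernel(np.array([0.0]), np.array([r]), p)
        assert abs(val - np.exp(-(r**2) / 2.0)) < 1e-6

    def test_dimension_mismatch_rejected(self):
        p = RQKernelParams(length_scale=1.0)
        with pytest.raises(InputError):
            rq_kernel(np.zeros(2), np.zeros(3), p)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            RQKernelParams(length_scale=-1.0)
        with pytest.raises(ParameterError):
            RQKernelParams(length_scale=1.0, alpha=0.0)

    @pytest.mark.parametrize("tag", KERNEL_TAGS)
    def test_gram_matrices_psd(self, tag):
        X = np.random.default_rng(0).normal(size=(50, 4))
        K = kernel_matrix(X, X, tag, l=1.3, alpha=0.8, signal_sd=2.0)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestGPRFit:
    def test_constant_targets_give_constant_predictions(self):
        r = np.random.default_rng(1)
        X = r.normal(size=(20, 3))
        y = np.full(20, 75.0)
        model = fit_gpr(X, y, "rq", seed=0, n_restarts=1)
        assert model.beta == pytest.approx(75.0, abs=1e-6)
        mean, _ = predict_gpr(model, r.normal(size=(5, 3)))
        np.testing.assert_allclose(mean, 75.0, atol=1e-4)

    def test_noiseless_interpolation(self):
        X = np.linspace(0, 1, 30)[:, None]
        y = np.sin(4 * X[:, 0]) * 10 + 50
        model = fit_gpr(
            X, y, "rq", seed=0, n_restarts=1,
            fixed_params=RQKernelParams(0.3, 1.0, float(np.std(y)), 1e-8),
        )
        mean, _ = predict_gpr(model, X)
        np.testing.assert_allclose(mean, y, atol=1e-4)

    def test_far_inputs_revert_to_basis_and_signal_sd(self):
        p = RQKernelParams(0.5, 1.0, 3.0, 1e-4)
        X = np.random.default_rng(2).normal(size=(15, 2))
        y = np.random.default_rng(3).normal(size=15) * 3 + 100
        model = fit_gpr(X, y, "rq", fixed_params=p)
        mean, sd = predict_gpr(model, np.full((1, 2), 1e4))
        assert mean[0] == pytest.approx(model.beta, abs=1e-6)
        assert sd[0] == pytest.approx(3.0, abs=1e-6)

    def test_duplicate_inputs_predict_identically(self):
        r = np.random.default_rng(4)
        X, y = r.normal(size=(25, 3)), r.normal(size=25)
        model = fit_gpr(X, y, "rq", seed=0, n_restarts=1)
        mean, sd = predict_gpr(model, np.vstack([X[:2], X[:2]]))
        np.testing.assert_array_equal(mean[:2], mean[2:])
        np.testing.assert_array_equal(sd[:2], sd[2:])

    def test_permutation_invariance(self):
        r = np.random.default_rng(5)
        X, y = r.normal(size=(30, 4)), r.normal(size=30) * 20
        perm = r.permutation(30)
        p = RQKernelParams(1.0, 0.7, 15.0, 0.5)
        m1 = fit_gpr(X, y, "rq", fixed_params=p)
        m2 = fit_gpr(X[perm], y[perm], "rq", fixed_params=p)
        Xnew = r.normal(size=(6, 4))
        np.testing.assert_allclose(predict_gpr(m1, Xnew)[0], predict_gpr(m2, Xnew)[0], atol=1e-8)

    def test_budget_exceeded_suggests_subsampling(self):
        X = np.zeros((11, 2))
        with pytest.raises(FitError, match="subsample"):
            fit_gpr(X, np.zeros(11), max_train=10)

    def test_dimension_mismatch_on_predict(self):
        model = fit_gpr(
            np.random.default_rng(0).normal(size=(10, 3)), np.arange(10.0),
            fixed_params=RQKernelParams(1.0, 1.0, 1.0, 0.1),
        )
        with pytest.raises(InputError):
            predict_gpr(model, np.zeros((2, 4)))

    def test_matches_sklearn_at_fixed_hyperparameters(self):
        """Independent cross-check: exact-GP posterior mean against sklearn's
        GaussianProcessRegressor with the same RQ kernel, after removing the
        constant basis."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RationalQuadratic, WhiteKernel

        r = np.random.default_rng(6)
        X, y = r.normal(size=(40, 3)), r.normal(size=40) * 5 + 30
        p = RQKernelParams(length_scale=1.2, alpha=0.8, signal_sd=1.0, noise_sd=0.3)
        mine = fit_gpr(X, y, "rq", fixed_params=p)

        k = RationalQuadratic(length_scale=1.2, alpha=0.8) + WhiteKernel(0.09)
        sk = GaussianProcessRegressor(kernel=k, optimizer=None, alpha=1e-10)
        sk.fit(X, y - mine.beta)
        Xnew = r.normal(size=(8, 3))
        np.testing.assert_allclose(
            predict_gpr(mine, Xnew)[0], sk.predict(Xnew) + mine.beta, atol=1e-6
        )


class TestEvaluate:
    class _Identity:
        tag = "identity"

        def __init__(self, out):
            self.out = np.asarray(out, float)

        def predict(self, X):
            return self.out

    def test_perfect_prediction(self):
        y = np.array([0.0, 50.0, 100.0])
        rep = evaluate(self._Identity(y), np.zeros((3, 1)), y)
        assert rep.rmse == 0.0 and rep.r2 == 1.0

    def test_mean_predictor_has_zero_r2(self):
        y = np.array([0.0, 50.0, 100.0])
        rep = evaluate(self._Identity(np.full(3, 50.0)), np.zeros((3, 1)), y)
        assert rep.r2 == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        rep = evaluate(self._Identity([3.0, 4.0]), np.zeros((2, 1)), np.array([0.0, 0.0]))
        assert rep.rmse == pytest.approx(np.sqrt(12.5))

    def test_rmse_consistent_with_residuals(self):
        r = np.random.default_rng(7)
        y, pred = r.normal(size=20), r.normal(size=20)
        rep = evaluate(self._Identity(pred), np.zeros((20, 1)), y)
        assert rep.rmse**2 == pytest.approx(np.mean(rep.residuals**2), rel=1e-9)
        np.testing.assert_array_equal(rep.residuals, y - pred)

    def test_zero_variance_targets_warns(self):
        with pytest.warns(UserWarning, match="undefined"):
            rep = evaluate(self._Identity([1.0, 2.0]), np.zeros((2, 1)), np.array([5.0, 5.0]))
        assert rep.r2 is None

    def test_per_concentration_medians(self):
        y = np.array([0.0, 0.0, 150.0, 150.0])
        rep = evaluate(self._Identity([1.0, 3.0, 140.0, 160.0]), np.zeros((4, 1)), y)
        assert rep.per_concentration_medians == {0.0: 2.0, 150.0: 150.0}


class TestProtocols:
    def _data(self, n=40, seed=0):
        r = np.random.default_rng(seed)
        y = np.repeat([0.0, 50.0, 100.0, 150.0], n // 4)
        X = y[:, None] / 150.0 + r.normal(0, 0.05, size=(n, 3))
        return X, y

    def test_stratified_split_covers_all_levels(self):
        X, y = self._data()
        _, _, y_tr, y_te = stratified_split(X, y, SplitSpec(seed=1))
        assert set(np.unique(y_tr)) == set(np.unique(y_te)) == {0.0, 50.0, 100.0, 150.0}

    def test_cv_deterministic_across_runs(self):
        X, y = self._data()
        spec = SplitSpec(cv_folds=5, seed=3)
        rep1, sum1 = cross_validate(X, y, RidgeLinearModel, spec)
        rep2, sum2 = cross_validate(X, y, RidgeLinearModel, spec)
        assert sum1 == sum2
        np.testing.assert_array_equal(rep1[0].residuals, rep2[0].residuals)

    def test_leave_one_out_boundary(self):
        X, y = self._data(n=12)[0][:10], self._data(n=12)[1][:10]
        reports, summary = cross_validate(X, y, RidgeLinearModel, SplitSpec(cv_folds=10, seed=0))
        assert len(reports) == 10 and np.isfinite(summary["rmse_mean"])

    def test_collinear_features_stay_finite(self):
        r = np.random.default_rng(8)
        base = r.normal(size=(20, 1))
        X = np.hstack([base, base, base])  # exactly collinear
        y = base[:, 0] * 10
        models = fit_baselines(X, y)
        assert np.all(np.isfinite(models["linear-ridge"].predict(X)))

    def test_tree_on_single_concentration_is_constant(self):
        X = np.random.default_rng(9).normal(size=(15, 4))
        y = np.full(15, 100.0)
        tree = RegressionTreeModel().fit(X, y)
        np.testing.assert_array_equal(tree.predict(X), 100.0)

    def test_loco_absent_level_rejected(self):
        X, y = self._data()
        with pytest.raises(InputError):
            leave_one_concentration_out(X, y, 75.0, RidgeLinearModel)

    def test_loco_interpolates_between_neighbours(self):
        X, y = self._data(n=80, seed=10)
        report, deviation = leave_one_concentration_out(X, y, 100.0, RidgeLinearModel)
        assert isinstance(report, EvalReport)
        # features are monotone in concentration, so the held-out group must
        # land between its neighbours
        assert 50.0 < 100.0 + deviation < 150.0

    def test_predict_week_single_model(self):
        model = self.FixedMedian(42.0)
        week, table = predict_week({4: model}, np.zeros((3, 2)), 100.0)
        assert week == 4 and set(table) == {4}

    def test_predict_week_tie_breaks_earlier(self):
        models = {3: self.FixedMedian(120.0), 2: self.FixedMedian(80.0)}
        week, table = predict_week(models, np.zeros((3, 2)), 100.0)
        assert table[2] == table[3] == 20.0
        assert week == 2

    def test_predict_week_empty_map_rejected(self):
        with pytest.raises(InputError):
            predict_week({}, np.zeros((2, 2)), 100.0)

    class FixedMedian:
        def __init__(self, value):
            self.value = value

        def predict(self, X):
            return np.full(len(X), self.value)


class TestGPRFactory:
    def test_fits_through_common_interface(self):
        r = np.random.default_rng(11)
        X = r.normal(size=(25, 2))
        y = X[:, 0] * 30 + 50
        factory = GPRFactory(kernel_tag="rq", seed=0, n_restarts=1)
        factory.fit(X, y)
        rep = evaluate(factory, X, y)
        assert rep.rmse < 5.0

    def test_predict_before_fit_rejected(self):
        with pytest.raises(InputError):
            GPRFactory().predict(np.zeros((2, 2)))
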