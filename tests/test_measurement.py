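"""Likelihood families: fluorescence, ordinal, nominal and GP."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from mml.measurement import (
    Dataset,
    DatasetBundle,
    FluorescenceNoiseModel,
    GPModelParams,
    MisclassificationModel,
    NominalModelParams,
    OrdinalModelParams,
    composite_loglik,
    fluorescence_loglik,
    gp_gram,
    gp_log_marginal_loglik,
    gp_posterior_mean,
    nominal_loglik,
    nominal_prob,
    ordinal_category_probs,
    ordinal_loglik,
    rbf_ard_kernel,
)

rng = np.random.default_rng(1234)


class TestFluorescence:
    def test_zero_residual_scores_zero(self):
        y = rng.random(10)
        noise = FluorescenceNoiseModel(np.full(10, 0.1))
        assert fluorescence_loglik(y, y, noise) == 0.0

    def test_single_point_direct_value(self):
        noise = FluorescenceNoiseModel(np.array([0.1]))
        assert fluorescence_loglik(np.array([0.5]), np.array([0.6]), noise) \
            == pytest.approx(-0.5)

    def test_matches_loop_oracle(self):
        pred, data = rng.random(20), rng.random(20)
        sd = 0.05 + rng.random(20) * 0.1
        oracle = sum(-(d - p) ** 2 / (2 * s ** 2)
                     for p, d, s in zip(pred, data, sd))
        assert fluorescence_loglik(pred, data, FluorescenceNoiseModel(sd)) \
            == pytest.approx(oracle)

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            FluorescenceNoiseModel(np.array([0.1, 0.0]))


class TestOrdinalProbs:
    @settings(deadline=None, max_examples=50)
    @given(x=st.floats(-2, 3), alpha=st.floats(0, 80),
           thetas=st.lists(st.floats(0.01, 0.5), min_size=1, max_size=6))
    def test_probabilities_form_a_simplex(self, x, alpha, thetas):
        params = OrdinalModelParams(alpha=alpha, theta_distances=np.array(thetas))
        p = ordinal_category_probs(np.array([x]), params)[0]
        assert np.all(p >= -1e-12)
        assert p.sum() == pytest.approx(1.0)

    def test_zero_slope_makes_probs_independent_of_x(self):
        params = OrdinalModelParams(alpha=0.0, theta_distances=np.array([0.2, 0.3]))
        pa = ordinal_category_probs(np.array([0.0]), params)
        pb = ordinal_category_probs(np.array([0.9]), params)
        np.testing.assert_allclose(pa, pb)

    def test_even_interval_parameterization_boundaries(self):
        """Equal 0.2 threshold spacing: each cumulative probability crosses
        50% exactly where the next category's range begins."""
        params = OrdinalModelParams(alpha=30.0, theta_distances=np.full(4, 0.2))
        from mml.measurement import logistic
        for j, beta in enumerate(params.betas):
            assert beta == pytest.approx(0.2 * (j + 1))
            cum = logistic(params.alpha * (beta - params.betas))
            assert cum[j] == pytest.approx(0.5)

    def test_cumulative_probs_nonincreasing_in_category(self):
        params = OrdinalModelParams(alpha=25.0,
                                    theta_distances=np.array([0.17, 0.24, 0.19, 0.22]))
        from mml.measurement import logistic
        for x in rng.random(5):
            cum = logistic(params.alpha * (x - params.betas))
            assert np.all(np.diff(cum) <= 1e-12)

    def test_nonpositive_theta_rejected(self):
        with pytest.raises(ValueError):
            OrdinalModelParams(alpha=1.0, theta_distances=np.array([0.2, -0.1]))


class TestMisclassification:
    def test_default_matrix_structure_exact(self):
        m = MisclassificationModel.default(5).matrix
        assert np.all(np.diag(m) == 0.95)
        for j in (1, 2, 3):
            assert m[j, j - 1] == 0.025 and m[j, j + 1] == 0.025
        assert m[0, 1] == 0.05 and m[4, 3] == 0.05
        np.testing.assert_allclose(m.sum(axis=1), 1.0)
        # no mass beyond adjacent categories
        assert m[0, 2] == 0.0 and m[2, 0] == 0.0

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError):
            MisclassificationModel(np.array([[0.9, 0.2], [0.1, 0.9]]))


class TestOrdinalLoglik:
    params = OrdinalModelParams(alpha=25.0,
                                theta_distances=np.array([0.17, 0.24, 0.19, 0.22]))

    def test_identity_error_matches_loop_oracle(self):
        x = rng.random(30)
        cats = rng.integers(0, 5, size=30)
        probs = ordinal_category_probs(x, self.params)
        oracle = sum(np.log(probs[i, c]) for i, c in enumerate(cats))
        val = ordinal_loglik(x, cats, self.params,
                             MisclassificationModel.identity(5))
        assert val == pytest.approx(oracle)

    def test_marginalization_by_enumeration(self):
        x = np.array([0.1, 0.5, 0.9])
        cats = np.array([0, 2, 4])
        err = MisclassificationModel.default(5)
        probs = ordinal_category_probs(x, self.params)
        oracle = 0.0
        for i, c in enumerate(cats):
            oracle += np.log(sum(err.matrix[j, c] * probs[i, j] for j in range(5)))
        assert ordinal_loglik(x, cats, self.params, err) == pytest.approx(oracle)

    def test_adjacent_category_never_minus_inf(self):
        # far in the top category's range, reporting the adjacent one
        val = ordinal_loglik(np.array([1.0]), np.array([3]), self.params,
                             MisclassificationModel.default(5))
        assert np.isfinite(val)

    def test_category_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ordinal_loglik(np.array([0.5]), np.array([7]), self.params)


class TestNominal:
    def test_all_zero_params_give_half(self):
        params = NominalModelParams(alpha=1.0, beta0=0.0, weights=np.zeros(3))
        assert nominal_prob(np.zeros(3), params) == pytest.approx(0.5)

    def test_monotone_in_positively_weighted_feature(self):
        params = NominalModelParams(alpha=2.0, beta0=0.0,
                                    weights=np.array([1.0, 0.0]))
        ps = [nominal_prob(np.array([x, 0.3]), params) for x in (0.1, 0.4, 0.9)]
        assert ps[0] < ps[1] < ps[2]

    def test_matches_sklearn_logistic_oracle(self):
        from sklearn.linear_model import LogisticRegression

        X = rng.normal(size=(40, 3))
        params = NominalModelParams(alpha=1.0, beta0=0.3,
                                    weights=np.array([0.8, -1.2, 0.4]))
        clf = LogisticRegression()
        clf.fit(X, rng.integers(0, 2, size=40))  # fit only to set shapes
        clf.coef_ = (params.alpha * params.weights)[None, :]
        clf.intercept_ = np.array([params.alpha * params.beta0])
        oracle = clf.predict_proba(X)[:, 1]
        np.testing.assert_allclose(nominal_prob(X, params), oracle, atol=1e-12)

    def test_uniform_probability_loglik(self):
        params = NominalModelParams(alpha=1.0, beta0=0.0, weights=np.zeros(2))
        X = rng.normal(size=(17, 2)) * 0.0
        outs = rng.choice(["death", "survival"], size=17)
        assert nominal_loglik(X, outs, params) == pytest.approx(17 * np.log(0.5))

    def test_single_death_observation(self):
        # p(death) = 0.9  <=>  z = logit(0.9)
        z = np.log(0.9 / 0.1)
        params = NominalModelParams(alpha=1.0, beta0=z, weights=np.zeros(1))
        assert nominal_loglik(np.zeros((1, 1)), np.array(["death"]), params) \
            == pytest.approx(np.log(0.9))

    def test_matches_bernoulli_loop_oracle(self):
        X = rng.normal(size=(50, 3))
        params = NominalModelParams(alpha=1.5, beta0=-0.2,
                                    weights=np.array([0.5, -0.8, 0.1]))
        p = nominal_prob(X, params)
        outs = np.where(rng.random(50) < 0.5, "death", "survival")
        oracle = sum(np.log(pi) if o == "death" else np.log(1 - pi)
                     for pi, o in zip(p, outs))
        assert nominal_loglik(X, outs, params) == pytest.approx(oracle)

    def test_bad_outcome_label_rejected(self):
        params = NominalModelParams(alpha=1.0, beta0=0.0, weights=np.zeros(1))
        with pytest.raises(ValueError):
            nominal_loglik(np.zeros((1, 1)), np.array(["necrosis"]), params)

    def test_feature_length_mismatch_rejected(self):
        params = NominalModelParams(alpha=1.0, beta0=0.0, weights=np.zeros(3))
        with pytest.raises(ValueError):
            nominal_prob(np.zeros(2), params)


class TestGP:
    def test_zero_distance_gives_amplitude(self):
        params = GPModelParams(sigma_f2=2.5, beta_weights=np.array([0.3, 0.7]))
        x = np.array([0.1, 0.2])
        assert rbf_ard_kernel(x, x, params) == pytest.approx(2.5)

    def test_symmetry_and_monotone_decay(self):
        params = GPModelParams(sigma_f2=1.0, beta_weights=np.array([0.5, 0.5]))
        a, b = rng.random(2), rng.random(2)
        assert rbf_ard_kernel(a, b, params) == pytest.approx(
            rbf_ard_kernel(b, a, params))
        base = np.zeros(2)
        vals = [rbf_ard_kernel(base, np.full(2, r), params)
                for r in (0.1, 0.5, 1.0)]
        assert vals[0] > vals[1] > vals[2]

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            GPModelParams(sigma_f2=1.0, beta_weights=np.array([0.5, 0.0]))

    def test_scalar_closed_form(self):
        params = GPModelParams(sigma_f2=0.8, beta_weights=np.array([1.0]),
                               sigma_y=0.1)
        y = np.array([0.4])
        v = 0.8 + 0.01
        expected = -0.5 * y[0] ** 2 / v - 0.5 * np.log(v) - 0.5 * np.log(2 * np.pi)
        assert gp_log_marginal_loglik(np.array([[0.2]]), y, params) \
            == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_matches_multivariate_normal_oracle(self, n):
        X = rng.random((n, 3))
        y = rng.random(n)
        params = GPModelParams(sigma_f2=0.5, beta_weights=np.array([0.4, 0.6, 1.1]),
                               sigma_y=0.05)
        K = gp_gram(X, params)
        oracle = multivariate_normal(mean=np.zeros(n), cov=K).logpdf(y)
        assert gp_log_marginal_loglik(X, y, params) == pytest.approx(oracle, abs=1e-8)

    def test_matches_sklearn_gpr_marginal(self):
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

        X = rng.random((6, 2))
        y = rng.random(6) - 0.5
        beta = np.array([0.4, 0.9])
        params = GPModelParams(sigma_f2=0.7, beta_weights=beta, sigma_y=0.1)
        kernel = ConstantKernel(0.7, "fixed") * RBF(beta, "fixed") \
            + WhiteKernel(0.01, "fixed")
        gpr = GaussianProcessRegressor(kernel=kernel, optimizer=None)
        gpr.fit(X, y)
        assert gp_log_marginal_loglik(X, y, params) \
            == pytest.approx(gpr.log_marginal_likelihood(), abs=1e-6)

    def test_permutation_invariance(self):
        X = rng.random((5, 2))
        y = rng.random(5)
        params = GPModelParams(sigma_f2=1.2, beta_weights=np.array([0.5, 0.8]),
                               sigma_y=0.05)
        perm = rng.permutation(5)
        assert gp_log_marginal_loglik(X, y, params) == pytest.approx(
            gp_log_marginal_loglik(X[perm], y[perm], params), abs=1e-10)

    def test_small_amplitude_limit_is_independent_noise(self):
        X = rng.random((4, 2))
        y = rng.random(4) * 0.1
        sy = 0.2
        params = GPModelParams(sigma_f2=1e-14, beta_weights=np.array([0.5, 0.8]),
                               sigma_y=sy)
        indep = np.sum(-0.5 * y ** 2 / sy ** 2 - 0.5 * np.log(2 * np.pi * sy ** 2))
        assert gp_log_marginal_loglik(X, y, params) == pytest.approx(indep, rel=1e-6)

    def test_posterior_mean_interpolates_as_noise_vanishes(self):
        X = rng.random((4, 2))
        y = rng.random(4)
        params = GPModelParams(sigma_f2=1.0, beta_weights=np.array([0.5, 0.8]),
                               sigma_y=1e-3)
        mean = gp_posterior_mean(X, y, X, params)
        np.testing.assert_allclose(mean, y, atol=1e-3)


class TestComposite:
    def _toy_bundle(self):
        pred = np.linspace(0, 1, 100)
        import pandas as pd

        from conftest import make_trajectory
        traj = make_trajectory(pred)
        data1 = pd.DataFrame({"time_s": traj.times[::10], "observable": "tBID",
                              "value": np.linspace(0, 1, 10), "sd": 0.1})
        ds1 = Dataset("fluorescence", data1,
                      FluorescenceNoiseModel(np.full(10, 0.1)))
        data2 = pd.DataFrame({"time_s": traj.times[::20], "observable": "tBID",
                              "category": [0, 0, 1, 2, 3]})
        params = OrdinalModelParams(alpha=25.0,
                                    theta_distances=np.array([0.2, 0.2, 0.2, 0.2]))
        ds2 = Dataset("ordinal", data2, {"tBID": params},
                      {"tBID": MisclassificationModel.default(5)})
        return traj, ds1, ds2

    def test_single_dataset_identity(self):
        traj, ds1, _ = self._toy_bundle()
        total = composite_loglik(DatasetBundle([ds1]), trajectory=traj)
        pred = np.interp(ds1.data["time_s"], traj.times,
                         traj.observable("tBID") / traj.observable("tBID").max())
        direct = fluorescence_loglik(pred, ds1.data["value"].to_numpy(), ds1.model)
        assert total == pytest.approx(direct)

    def test_order_invariance_and_additivity(self):
        traj, ds1, ds2 = self._toy_bundle()
        ab = composite_loglik(DatasetBundle([ds1, ds2]), trajectory=traj)
        ba = composite_loglik(DatasetBundle([ds2, ds1]), trajectory=traj)
        a = composite_loglik(DatasetBundle([ds1]), trajectory=traj)
        b = composite_loglik(DatasetBundle([ds2]), trajectory=traj)
        assert ab == pytest.approx(ba)
        assert ab == pytest.approx(a + b)

    def test_missing_model_is_configuration_error(self):
        traj, ds1, _ = self._toy_bundle()
        ds1.model = None
        with pytest.raises(ValueError):
            composite_loglik(DatasetBundle([ds1]), trajectory=traj)
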