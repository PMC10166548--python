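"""Posterior-predictive summaries: regions, areas, bands, weights, GP predictions."""

import numpy as np
import pytest

from mml.calibrate import ChainArchive
from mml.measurement import (
    GPModelParams,
    NominalModelParams,
    OrdinalModelParams,
    gp_gram,
    nominal_prob,
    ordinal_category_probs,
)
from mml.posterior import (
    credible_area,
    credible_region,
    credible_region_from_draws,
    decision_boundary,
    feature_weight_posterior,
    ordinal_probability_bands,
    population_density_contour,
    predict_fractional_cell_death,
)

rng = np.random.default_rng(99)


def make_archive(samples: np.ndarray, names: list[str]) -> ChainArchive:
    """Archive whose latter-half pool equals `samples` (replicated per chain)."""
    n = samples.shape[0]
    traces = np.tile(samples[None, :, :], (4, 2, 1))  # 2n steps; latter half = samples
    return ChainArchive(names=names, traces=traces,
                        logposts=np.zeros((4, traces.shape[1])),
                        past_states=samples, burn_in=0, converged=True)


class TestCredibleRegion:
    times = np.linspace(0, 1, 100)

    def test_point_mass_posterior_zero_width(self):
        row = np.array([2.0])
        arc = make_archive(np.tile(row, (30, 1)), ["a"])
        region = credible_region(arc, lambda r: np.full(100, r[0]), self.times,
                                 n_draws=20, seed=0)
        np.testing.assert_allclose(region.lower, region.upper)
        np.testing.assert_allclose(region.median, 2.0)

    def test_quantiles_match_sort_oracle(self):
        curves = rng.random((50, 100))
        region = credible_region_from_draws(self.times, curves)
        for t in (0, 37, 99):
            col = np.sort(curves[:, t])
            assert region.lower[t] == pytest.approx(np.quantile(col, 0.025))
            assert region.upper[t] == pytest.approx(np.quantile(col, 0.975))

    def test_gaussian_ensemble_coverage(self):
        curves = rng.normal(size=(2000, 100))
        region = credible_region_from_draws(self.times, curves)
        fresh = rng.normal(size=100)
        inside = np.mean((fresh >= region.lower) & (fresh <= region.upper))
        assert inside > 0.90

    def test_small_pool_samples_with_replacement_and_warns(self):
        arc = make_archive(rng.random((5, 1)), ["a"])
        with pytest.warns(UserWarning):
            credible_region(arc, lambda r: np.full(100, r[0]), self.times,
                            n_draws=50, seed=1)


class TestCredibleArea:
    def test_constant_band_width(self):
        times = np.linspace(0, 1, 100)
        region = credible_region_from_draws(
            times, np.vstack([np.zeros(100), np.ones(100)] * 30))
        w = region.upper - region.lower
        np.testing.assert_allclose(w, w[0])  # constant width
        assert credible_area(region) == pytest.approx(100 * w[0])

    def test_zero_width_region(self):
        times = np.linspace(0, 1, 100)
        region = credible_region_from_draws(times, np.tile(rng.random(100), (20, 1)))
        assert credible_area(region) == 0.0

    def test_matches_loop_oracle(self):
        times = np.linspace(0, 1, 100)
        curves = rng.random((40, 100))
        region = credible_region_from_draws(times, curves)
        oracle = sum(region.upper[t] - region.lower[t] for t in range(100))
        assert credible_area(region) == pytest.approx(oracle)

    def test_monotone_in_dispersion(self):
        times = np.linspace(0, 1, 100)
        base = rng.normal(size=(400, 100))
        wide = credible_region_from_draws(times, base)
        narrow = credible_region_from_draws(times, 0.3 * base)
        assert credible_area(narrow) < credible_area(wide)

    def test_wrong_grid_rejected(self):
        region = credible_region_from_draws(np.linspace(0, 1, 50),
                                            rng.random((10, 50)))
        with pytest.raises(ValueError):
            credible_area(region)


class TestOrdinalBands:
    names = ["alpha", "t0", "t1", "t2", "t3"]

    @staticmethod
    def builder(row):
        return OrdinalModelParams(alpha=row[0], theta_distances=row[1:5])

    def test_point_mass_collapses_to_single_model(self):
        row = np.array([25.0, 0.17, 0.24, 0.19, 0.22])
        arc = make_archive(np.tile(row, (40, 1)), self.names)
        bands = ordinal_probability_bands(arc, self.builder, n_draws=20, seed=0)
        direct = ordinal_category_probs(bands["x"], self.builder(row)).T
        np.testing.assert_allclose(bands["lower"], direct, atol=1e-12)
        np.testing.assert_allclose(bands["upper"], direct, atol=1e-12)

    def test_envelopes_bounded_and_median_simplex(self):
        samples = np.column_stack(
            [rng.uniform(18, 30, 100)]
            + [rng.uniform(0.15, 0.25, 100) for _ in range(4)])
        arc = make_archive(samples, self.names)
        bands = ordinal_probability_bands(arc, self.builder, n_draws=80, seed=1)
        assert np.all(bands["lower"] >= -1e-12)
        assert np.all(bands["upper"] <= 1 + 1e-12)
        # pointwise medians per category are not a simplex by construction,
        # but for a concentrated posterior they stay close to one
        sums = bands["median"].sum(axis=0)
        assert np.all(np.abs(sums - 1.0) < 0.2)

    def test_truth_inside_bands_when_truth_in_sample(self):
        truth_row = np.array([25.0, 0.17, 0.24, 0.19, 0.22])
        samples = truth_row + rng.normal(0, 0.01, size=(60, 5)) * [1, 1, 1, 1, 1]
        samples = np.vstack([samples, truth_row])
        arc = make_archive(np.abs(samples), self.names)
        bands = ordinal_probability_bands(arc, self.builder, n_draws=61, seed=2)
        truth_curves = ordinal_category_probs(bands["x"], self.builder(truth_row)).T
        assert np.all(truth_curves >= bands["lower"] - 1e-9)
        assert np.all(truth_curves <= bands["upper"] + 1e-9)


class TestDecisionBoundary:
    def test_antisymmetric_weights_give_diagonal(self):
        params = NominalModelParams(alpha=1.0, beta0=0.0,
                                    weights=np.array([1.0, -1.0]))
        pts = decision_boundary(params)
        np.testing.assert_allclose(pts[:, 0], pts[:, 1])

    def test_zero_weight_gives_axis_aligned_boundary(self):
        params = NominalModelParams(alpha=2.0, beta0=-0.3,
                                    weights=np.array([0.6, 0.0]))
        pts = decision_boundary(params)
        np.testing.assert_allclose(pts[:, 0], 0.5)  # x = -beta0/w0

    def test_boundary_points_evaluate_to_half(self):
        params = NominalModelParams(alpha=3.0, beta0=0.1,
                                    weights=np.array([0.7, -0.4, 0.2]))
        fixed = np.array([0.0, 0.0, 0.5])
        pts = decision_boundary(params, plane=(0, 1), fixed_features=fixed)
        for x0, x1 in pts[::10]:
            p = nominal_prob(np.array([x0, x1, 0.5]), params)
            assert p == pytest.approx(0.5, abs=1e-9)

    def test_no_boundary_signaled(self):
        params = NominalModelParams(alpha=1.0, beta0=0.0,
                                    weights=np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            decision_boundary(params, plane=(0, 1))


class TestWeightPosterior:
    def test_sign_flip_invariance(self):
        names = ["nom_alpha", "nom_w0", "nom_w1"]
        samples = rng.normal(size=(50, 3))
        flipped = -samples
        a = feature_weight_posterior(make_archive(samples, names),
                                     "nom_alpha", ["nom_w0", "nom_w1"])
        b = feature_weight_posterior(make_archive(flipped, names),
                                     "nom_alpha", ["nom_w0", "nom_w1"])
        np.testing.assert_allclose(a.samples, b.samples)
        # and the probabilities themselves are unchanged under the flip
        p1 = nominal_prob(np.array([0.3, 0.7]), NominalModelParams(
            alpha=samples[0, 0], beta0=0.2, weights=samples[0, 1:]))
        p2 = nominal_prob(np.array([0.3, 0.7]), NominalModelParams(
            alpha=-samples[0, 0], beta0=-0.2, weights=-samples[0, 1:]))
        assert p1 == pytest.approx(p2)

    def test_ranking_by_median_magnitude(self):
        names = ["a", "w0", "w1"]
        samples = np.column_stack([np.ones(30),
                                   rng.normal(5, 0.1, 30),
                                   rng.normal(0, 0.1, 30)])
        wp = feature_weight_posterior(make_archive(samples, names), "a",
                                      ["w0", "w1"])
        assert wp.ranking() == ["w0", "w1"]


class TestFractionalPrediction:
    def test_noise_free_query_at_training_point(self):
        X = rng.random((4, 2))
        y = rng.random(4)
        names = ["dummy"]
        arc = make_archive(np.zeros((30, 1)), names)

        def features(row):
            return X, y, X[:1]

        def gp(row):
            return GPModelParams(sigma_f2=1.0,
                                 beta_weights=np.array([0.5, 0.8]),
                                 sigma_y=1e-3)

        preds = predict_fractional_cell_death(arc, features, gp, n_draws=10,
                                              seed=0)
        np.testing.assert_allclose(preds, y[0], atol=1e-2)

    def test_matches_dense_gp_conditioning_oracle(self):
        X = rng.random((3, 2))
        y = rng.random(3)
        Xq = rng.random((2, 2))
        params = GPModelParams(sigma_f2=0.9, beta_weights=np.array([0.4, 0.7]),
                               sigma_y=0.05)
        K = gp_gram(X, params)
        Kq = np.array([[0.9 * np.exp(-0.5 * np.sum(((q - x) / params.beta_weights) ** 2))
                        for x in X] for q in Xq])
        oracle = Kq @ np.linalg.solve(K, y)
        arc = make_archive(np.zeros((30, 1)), ["dummy"])
        preds = predict_fractional_cell_death(
            arc, lambda row: (X, y, Xq), lambda row: params, n_draws=5, seed=1)
        np.testing.assert_allclose(preds[0], np.clip(oracle, 0, 1), atol=1e-8)

    def test_predictions_clamped_to_unit_interval(self):
        X = rng.random((3, 1))
        y = np.array([5.0, -3.0, 2.0])  # out-of-range training values
        arc = make_archive(np.zeros((10, 1)), ["dummy"])
        preds = predict_fractional_cell_death(
            arc, lambda row: (X, y, X),
            lambda row: GPModelParams(sigma_f2=4.0,
                                      beta_weights=np.array([0.5]),
                                      sigma_y=1e-3),
            n_draws=5, seed=2)
        assert np.all((preds >= 0.0) & (preds <= 1.0))


class TestDensityContour:
    def test_mass_concentrates_inside_contour(self):
        pts = rng.normal(size=(500, 2))
        out = population_density_contour(pts, level=0.05)
        assert out["mask"].any() and not out["mask"].all()
        # the high-density mask covers the origin
        ix = np.argmin(np.abs(out["x"]))
        iy = np.argmin(np.abs(out["y"]))
        assert out["mask"][iy, ix] or out["mask"][ix, iy]
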