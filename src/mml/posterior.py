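"""Posterior-predictive summaries of calibrated models.

The central uncertainty summary is the 95% credible region of predicted
normalized dynamics: 1000 parameter draws from the posterior sample are
re-simulated and pointwise 0.025/0.975 quantiles taken over the 100-point
grid.  The region's area (sum of band widths across the grid) is the model
certainty metric — smaller area, higher certainty.

Measurement-model posteriors get their own summaries: per-category ordinal
probability envelopes as a function of the normalized measurand, the 50%
cell-death decision boundary of the logistic fate model, effective feature
weights (slope x coefficient), kernel-density contours of simulated feature
populations, and GP posterior-mean predictions of fractional cell death.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from mml.calibrate import ChainArchive
from mml.measurement import (
    GPModelParams,
    NominalModelParams,
    OrdinalModelParams,
    gp_posterior_mean,
    nominal_prob,
    ordinal_category_probs,
)

__all__ = [
    "CredibleRegion",
    "WeightPosterior",
    "credible_region",
    "credible_region_from_draws",
    "credible_area",
    "ordinal_probability_bands",
    "decision_boundary",
    "feature_weight_posterior",
    "population_density_contour",
    "predict_fractional_cell_death",
]


@dataclass
class CredibleRegion:
    """Pointwise 95% envelope (0.025/0.975 quantiles) plus the median."""

    times: np.ndarray
    lower: np.ndarray
    median: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        if np.any(self.lower > self.median + 1e-12) or \
                np.any(self.median > self.upper + 1e-12):
            raise ValueError("envelopes must be ordered lower <= median <= upper")

    def contains(self, values: np.ndarray) -> bool:
        """True if a reference curve lies inside the band at every point."""
        return bool(np.all((values >= self.lower) & (values <= self.upper)))


@dataclass
class WeightPosterior:
    """Posterior sample of effective feature weights (slope x coefficient)."""

    feature_names: list[str]
    samples: np.ndarray  # (n_draws, n_features)

    def median_abs_weight(self) -> np.ndarray:
        return np.median(np.abs(self.samples), axis=0)

    def ranking(self) -> list[str]:
        """Feature names ordered most- to least-predictive."""
        order = np.argsort(self.median_abs_weight())[::-1]
        return [self.feature_names[i] for i in order]


def _draw_rows(archive: ChainArchive, n_draws: int,
               rng: np.random.Generator) -> np.ndarray:
    pool = archive.posterior_samples()
    if len(pool) < n_draws:
        warnings.warn(
            f"only {len(pool)} retained samples for {n_draws} draws; "
            "sampling with replacement", stacklevel=2)
        idx = rng.integers(0, len(pool), size=n_draws)
    else:
        idx = rng.choice(len(pool), size=n_draws, replace=False)
    return pool[idx]


def credible_region_from_draws(times: np.ndarray, curves: np.ndarray
                               ) -> CredibleRegion:
    """Quantile envelope of a (n_draws, n_times) stack of predicted curves.

    Quantiles are type-7 (linear interpolation of order statistics), the
    numpy default, for bit-stable summaries.
    """
    curves = np.asarray(curves, dtype=float)
    lo, med, hi = np.quantile(curves, [0.025, 0.5, 0.975], axis=0)
    return CredibleRegion(times=np.asarray(times, float), lower=lo,
                          median=med, upper=hi)


def credible_region(archive: ChainArchive,
                    predict: Callable[[np.ndarray], np.ndarray],
                    times: np.ndarray,
                    n_draws: int = 1000,
                    seed: int = 0) -> CredibleRegion:
    """95% credible region of a predicted quantity.

    ``predict`` maps one posterior parameter vector to the predicted curve on
    ``times`` (e.g. re-simulating the model and normalizing an observable).
    Draws that fail to simulate are skipped.
    """
    rng = np.random.default_rng(seed)
    draws = _draw_rows(archive, n_draws, rng)
    curves = []
    for row in draws:
        try:
            curves.append(np.asarray(predict(row), dtype=float))
        except Exception:
            continue
    if not curves:
        raise RuntimeError("no posterior draw produced a valid prediction")
    return credible_region_from_draws(times, np.array(curves))


def credible_area(region: CredibleRegion, n_points: int = 100) -> float:
    """Sum of 95%-band widths across the standard grid (certainty metric)."""
    if region.times.size != n_points:
        raise ValueError(f"region must be on the standard {n_points}-point grid")
    return float(np.sum(region.upper - region.lower))


def ordinal_probability_bands(archive: ChainArchive,
                              param_builder: Callable[[np.ndarray], OrdinalModelParams],
                              x_grid: np.ndarray | None = None,
                              n_draws: int = 1000,
                              seed: int = 0) -> dict[str, np.ndarray]:
    """Per-category 95% envelopes of class probability vs normalized measurand.

    ``param_builder`` extracts the ordinal measurement parameters from one
    posterior row.  Returns arrays of shape (n_categories, len(x_grid)).
    """
    x = np.linspace(0.0, 1.0, 101) if x_grid is None else np.asarray(x_grid, float)
    rng = np.random.default_rng(seed)
    draws = _draw_rows(archive, n_draws, rng)
    stack = np.array([ordinal_category_probs(x, param_builder(row)).T
                      for row in draws])  # (draws, J, nx)
    lo, med, hi = np.quantile(stack, [0.025, 0.5, 0.975], axis=0)
    return {"x": x, "lower": lo, "median": med, "upper": hi}


def decision_boundary(params: NominalModelParams,
                      plane: tuple[int, int] = (0, 1),
                      fixed_features: np.ndarray | None = None,
                      x_values: np.ndarray | None = None) -> np.ndarray:
    """50%-probability locus of the logistic fate model in a 2-feature plane.

    For the linear model the locus satisfies beta0 + sum beta_l x_l = 0; with
    features outside the plane held fixed this is a line.  Returns (n, 2)
    points (x_i, x_j).  If both plane weights are zero there is no boundary.
    """
    i, j = plane
    w = params.weights
    fixed = np.zeros_like(w) if fixed_features is None else np.asarray(fixed_features)
    if w[i] == 0 and w[j] == 0:
        raise ValueError("both plotting weights are zero: no decision boundary")
    others = [l for l in range(w.size) if l not in (i, j)]
    c = params.beta0 + sum(w[l] * fixed[l] for l in others)
    x = np.linspace(0.0, 1.0, 51) if x_values is None else np.asarray(x_values)
    if w[j] != 0:
        yj = -(c + w[i] * x) / w[j]
        return np.column_stack([x, yj])
    xi = np.full_like(x, -c / w[i])  # vertical line
    return np.column_stack([xi, x])


def feature_weight_posterior(archive: ChainArchive,
                             slope_name: str,
                             weight_names: Sequence[str]) -> WeightPosterior:
    """Per-draw effective weights alpha * beta_l of the fate model features.

    The product is invariant to the joint sign flip (alpha, beta) ->
    (-alpha, -beta) that leaves every predicted probability unchanged, so it
    is the identifiable quantity; ranking by median |weight| orders features
    by predictive importance.
    """
    pool = archive.posterior_samples()
    cols = {n: archive.names.index(n) for n in (slope_name, *weight_names)}
    alpha = pool[:, cols[slope_name]]
    weights = np.column_stack([alpha * pool[:, cols[n]] for n in weight_names])
    return WeightPosterior(feature_names=list(weight_names), samples=weights)


def population_density_contour(points: np.ndarray, level: float = 0.05,
                               grid_size: int = 60) -> dict[str, np.ndarray]:
    """Gaussian-KDE density field of a simulated 2-D feature population.

    Scott's-rule bandwidth; the returned mask marks grid cells above the
    requested density level (the 0.05 contour used for population plots).
    """
    pts = np.asarray(points, dtype=float)
    kde = gaussian_kde(pts.T)
    lo = pts.min(axis=0) - 0.1 * np.ptp(pts, axis=0)
    hi = pts.max(axis=0) + 0.1 * np.ptp(pts, axis=0)
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    X, Y = np.meshgrid(gx, gy)
    Z = kde(np.vstack([X.ravel(), Y.ravel()])).reshape(grid_size, grid_size)
    return {"x": gx, "y": gy, "density": Z, "mask": Z >= level}


def predict_fractional_cell_death(
        archive: ChainArchive,
        predict_features: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray, np.ndarray]],
        gp_builder: Callable[[np.ndarray], GPModelParams],
        n_draws: int = 1000,
        seed: int = 0) -> np.ndarray:
    """Posterior predictive sample of mean fractional cell death per condition.

    For each posterior draw, ``predict_features`` returns (training features,
    training fractions, query features) under that parameter vector; the GP
    posterior mean conditioned on the training set is evaluated at the query
    conditions.  Predictions are clamped to [0, 1] (the GP itself is
    unconstrained).  Returns (n_successful_draws, n_conditions).
    """
    rng = np.random.default_rng(seed)
    draws = _draw_rows(archive, n_draws, rng)
    out = []
    for row in draws:
        try:
            train_x, train_y, query_x = predict_features(row)
            mean = gp_posterior_mean(train_x, train_y, query_x, gp_builder(row))
        except Exception:
            continue
        out.append(np.clip(mean, 0.0, 1.0))
    if not out:
        raise RuntimeError("no posterior draw produced a valid prediction")
    return np.array(out)
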