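"""Measurement-model likelihood families.

An explicit measurement model maps latent mechanistic variables x(t, theta)
to the values or category probabilities seen in data.  Four families cover
the data types used to constrain the apoptosis model:

fluorescence
    i.i.d. Gaussian noise on normalized trajectories; log L =
    sum -(yhat - y)^2 / (2 sigma^2).

ordinal (cumulative / proportional-odds model)
    ordinal values arise from a continuous latent measurand; the cumulative
    probability of reaching at least category c_j is a logistic function of
    the measurand with a shared slope alpha and monotone thresholds beta_j.
    Thresholds are parameterized by positive distances theta_j
    (beta_0 = theta_0, beta_j = beta_{j-1} + theta_j), so the ordering
    constraint holds by construction.  Reported categories may additionally
    be corrupted by a row-stochastic misclassification matrix (default 95%
    correct, 2.5% to each adjacent category).

nominal (logistic cell-fate model)
    the probability of a death outcome is a logistic function of a small
    feature vector extracted from single-cell dynamics; observations are
    independent Bernoulli draws with no misclassification.

fractional cell death (Gaussian-process regression)
    a zero-mean GP with an automatic-relevance radial-basis kernel maps
    per-condition feature vectors to mean fractional death; its log marginal
    likelihood scores the data without committing to a functional form.

A composite likelihood over a mixed dataset bundle is the sum of the
component log-likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from mml.mechanism import SimulationError, Trajectory

__all__ = [
    "FluorescenceNoiseModel",
    "OrdinalModelParams",
    "MisclassificationModel",
    "NominalModelParams",
    "GPModelParams",
    "Dataset",
    "DatasetBundle",
    "logistic",
    "normalize_signal",
    "fluorescence_loglik",
    "ordinal_category_probs",
    "ordinal_loglik",
    "ordinal_dataset_loglik",
    "nominal_prob",
    "nominal_loglik",
    "rbf_ard_kernel",
    "gp_gram",
    "gp_log_marginal_loglik",
    "composite_loglik",
]

DEATH, SURVIVAL = "death", "survival"


def logistic(z: np.ndarray) -> np.ndarray:
    """Standard logistic phi(z) = 1/(1+e^-z), overflow-safe."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def normalize_signal(values: np.ndarray) -> np.ndarray:
    """Scale a trajectory to [0, 1] by its own maximum.

    A flat (all-zero) trajectory cannot be normalized and marks the parameter
    vector as infeasible.
    """
    m = np.max(values)
    if not np.isfinite(m) or m <= 0:
        raise SimulationError("flat trajectory: cannot normalize")
    return np.asarray(values, dtype=float) / m


# ---------------------------------------------------------------------------
# fluorescence
# ---------------------------------------------------------------------------

@dataclass
class FluorescenceNoiseModel:
    """Per-point standard deviations of normalized fluorescence data."""

    sigma: np.ndarray

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive wherever data exist")


def fluorescence_loglik(pred: np.ndarray, data: np.ndarray,
                        noise: FluorescenceNoiseModel) -> float:
    """Gaussian log-likelihood of normalized measurements (kernel only).

    Matches the likelihood used for reporter time courses: the constant
    normalization term is dropped, so identical prediction and data score 0.
    """
    pred = np.asarray(pred, dtype=float)
    data = np.asarray(data, dtype=float)
    if pred.shape != data.shape or pred.shape != noise.sigma.shape:
        raise ValueError("pred, data and sigma must share a shape")
    r = (data - pred) / noise.sigma
    return float(-0.5 * np.sum(r * r))


# ---------------------------------------------------------------------------
# ordinal
# ---------------------------------------------------------------------------

@dataclass
class OrdinalModelParams:
    """Cumulative-model parameters for one ordinal observable.

    ``alpha`` is the shared slope; ``theta_distances`` are the J-1 positive
    distances between successive thresholds on the normalized measurand
    scale.  The cumulative probability of category >= c_j is
    phi(alpha * (x - beta_{j-1})) with beta = cumsum(theta).
    """

    alpha: float
    theta_distances: np.ndarray

    def __post_init__(self):
        self.theta_distances = np.atleast_1d(np.asarray(self.theta_distances, float))
        if self.theta_distances.size < 1:
            raise ValueError("need at least one threshold (J >= 2)")
        if np.any(self.theta_distances <= 0):
            raise ValueError("theta distances must be positive")

    @property
    def n_categories(self) -> int:
        return self.theta_distances.size + 1

    @property
    def betas(self) -> np.ndarray:
        """Monotone increasing thresholds beta_j."""
        return np.cumsum(self.theta_distances)


@dataclass
class MisclassificationModel:
    """Row-stochastic matrix P(reported category | true category)."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        J = self.matrix.shape[0]
        if self.matrix.shape != (J, J):
            raise ValueError("matrix must be square")
        if np.any(self.matrix < 0) or not np.allclose(self.matrix.sum(axis=1), 1.0):
            raise ValueError("rows must be nonnegative and sum to 1")

    @classmethod
    def default(cls, n_categories: int, p_error: float = 0.05) -> "MisclassificationModel":
        """95% correct, 2.5% to each adjacent category (5% at the ends)."""
        J = n_categories
        m = np.zeros((J, J))
        for j in range(J):
            m[j, j] = 1.0 - p_error
            neighbors = [j - 1, j + 1]
            neighbors = [a for a in neighbors if 0 <= a < J]
            for a in neighbors:
                m[j, a] = p_error / len(neighbors)
        return cls(m)

    @classmethod
    def identity(cls, n_categories: int) -> "MisclassificationModel":
        return cls(np.eye(n_categories))


def ordinal_category_probs(x: np.ndarray, params: OrdinalModelParams) -> np.ndarray:
    """Probability of each category given measurand values.

    Returns an array of shape (len(x), J); each row is a simplex.  The
    cumulative probabilities P(y >= c_j) telescope: P(y >= c_0) = 1 and
    P(y >= c_J) = 0, so the row sum is exactly 1.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    cum = logistic(params.alpha * (x[:, None] - params.betas[None, :]))
    ones = np.ones((x.size, 1))
    zeros = np.zeros((x.size, 1))
    cum_full = np.hstack([ones, cum, zeros])
    return cum_full[:, :-1] - cum_full[:, 1:]


def ordinal_loglik(x: np.ndarray, categories: np.ndarray,
                   params: OrdinalModelParams,
                   err: MisclassificationModel | None = None) -> float:
    """Log-likelihood of reported ordinal categories given measurand values.

    Marginalizes over the true category: log sum_j P(reported | true=c_j) *
    P(true=c_j | x).
    """
    categories = np.asarray(categories, dtype=int)
    J = params.n_categories
    if np.any(categories < 0) or np.any(categories >= J):
        raise ValueError(f"categories must lie in [0, {J})")
    probs = ordinal_category_probs(x, params)
    if err is not None:
        if err.matrix.shape[0] != J:
            raise ValueError("misclassification matrix size mismatch")
        probs = probs @ err.matrix
    p = probs[np.arange(categories.size), categories]
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(p)))


def ordinal_dataset_loglik(trajectory: Trajectory, data: pd.DataFrame,
                           params: dict[str, OrdinalModelParams],
                           err: dict[str, MisclassificationModel] | None = None,
                           ) -> float:
    """Ordinal log-likelihood of a tidy (time_s, observable, category) table.

    Each observable's trajectory is normalized to [0, 1] by its own maximum
    and linearly interpolated at the measurement times.
    """
    total = 0.0
    for obs, block in data.groupby("observable"):
        y = normalize_signal(trajectory.observable(obs))
        x = np.interp(block["time_s"].to_numpy(), trajectory.times, y)
        e = err.get(obs) if err else None
        total += ordinal_loglik(x, block["category"].to_numpy(), params[obs], e)
    return total


# ---------------------------------------------------------------------------
# nominal
# ---------------------------------------------------------------------------

@dataclass
class NominalModelParams:
    """Logistic cell-fate model: p(death) = phi(alpha * (beta0 + sum beta_l x_l))."""

    alpha: float
    beta0: float
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if not np.all(np.isfinite([self.alpha, self.beta0])) or \
                not np.all(np.isfinite(self.weights)):
            raise ValueError("nominal model parameters must be finite")

    @property
    def n_features(self) -> int:
        return self.weights.size


def nominal_prob(features: np.ndarray, params: NominalModelParams) -> np.ndarray:
    """Probability of the death outcome for one or many feature vectors."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != params.n_features:
        raise ValueError(
            f"expected {params.n_features} features, got {x.shape[1]}")
    p = logistic(params.alpha * (params.beta0 + x @ params.weights))
    return p if np.asarray(features).ndim > 1 else float(p[0])


def _encode_outcomes(outcomes: np.ndarray) -> np.ndarray:
    out = np.asarray(outcomes)
    if out.dtype.kind in "SUO":
        bad = ~np.isin(out, [DEATH, SURVIVAL])
        if np.any(bad):
            raise ValueError(f"outcomes must be {DEATH!r} or {SURVIVAL!r}")
        return (out == DEATH).astype(float)
    if not np.all(np.isin(out, [0, 1])):
        raise ValueError("numeric outcomes must be 0 (survival) or 1 (death)")
    return out.astype(float)


def nominal_loglik(features: np.ndarray, outcomes: np.ndarray,
                   params: NominalModelParams) -> float:
    """Bernoulli log-likelihood of death/survival records (no misclassification)."""
    y = _encode_outcomes(outcomes)
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[0] != y.size:
        raise ValueError("one feature vector per observation required")
    z = params.alpha * (params.beta0 + x @ params.weights)
    # log phi(z) = -log1p(exp(-z)); log(1-phi(z)) = -log1p(exp(z))
    return float(np.sum(-y * np.logaddexp(0.0, -z)
                        - (1.0 - y) * np.logaddexp(0.0, z)))


# ---------------------------------------------------------------------------
# Gaussian process (fractional cell death)
# ---------------------------------------------------------------------------

@dataclass
class GPModelParams:
    """ARD radial-basis kernel parameters.

    kappa(x_p, x_q) = sigma_f^2 exp(-1/2 (x_p - x_q)^T M (x_p - x_q)) with
    M = diag(beta)^-2; beta_l is the relevance weight of feature l (larger
    |beta_l| = longer length-scale = less relevant).  ``sigma_y`` is the
    per-observation noise sd added on the Gram diagonal only.
    """

    sigma_f2: float
    beta_weights: np.ndarray
    sigma_y: np.ndarray | float = 1e-3

    def __post_init__(self):
        if self.sigma_f2 <= 0:
            raise ValueError("sigma_f2 must be positive")
        self.beta_weights = np.atleast_1d(np.asarray(self.beta_weights, float))
        if np.any(self.beta_weights == 0):
            raise ValueError(
                "zero beta weight: mask the feature explicitly instead")


def rbf_ard_kernel(xp: np.ndarray, xq: np.ndarray, params: GPModelParams) -> float:
    """Noise-free kernel value between two feature vectors."""
    xp = np.asarray(xp, dtype=float)
    xq = np.asarray(xq, dtype=float)
    if xp.shape != xq.shape:
        raise ValueError("feature vectors must have equal length")
    d = (xp - xq) / params.beta_weights
    return float(params.sigma_f2 * np.exp(-0.5 * d @ d))


def gp_gram(features: np.ndarray, params: GPModelParams,
            with_noise: bool = True) -> np.ndarray:
    """Gram matrix of the ARD kernel; observation noise on the diagonal only."""
    x = np.atleast_2d(np.asarray(features, dtype=float)) / params.beta_weights
    sq = np.sum(x * x, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.clip(d2, 0.0, None, out=d2)
    K = params.sigma_f2 * np.exp(-0.5 * d2)
    if with_noise:
        sy = np.broadcast_to(np.asarray(params.sigma_y, float), (x.shape[0],))
        K = K + np.diag(np.maximum(sy, 1e-3) ** 2)
    return K


def _chol_with_jitter(K: np.ndarray):
    """Cholesky with escalating jitter; None after 3 doublings."""
    base = 1e-8 * np.trace(K) / K.shape[0]
    for jitter in (0.0, base, 2 * base, 4 * base, 8 * base):
        try:
            return cho_factor(K + jitter * np.eye(K.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            continue
    return None


def gp_log_marginal_loglik(features: np.ndarray, y: np.ndarray,
                           params: GPModelParams) -> float:
    """Zero-mean GP log marginal likelihood of fractional cell-death values.

    -1/2 y^T (K + sigma_y^2 I)^-1 y - 1/2 log|K + sigma_y^2 I| - n/2 log 2pi.
    Returns -inf if the Gram matrix is not positive definite after jitter.
    """
    y = np.asarray(y, dtype=float)
    K = gp_gram(features, params)
    chol = _chol_with_jitter(K)
    if chol is None:
        return -np.inf
    alpha = cho_solve(chol, y)
    logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
    return float(-0.5 * y @ alpha - 0.5 * logdet - 0.5 * y.size * np.log(2 * np.pi))


def gp_posterior_mean(train_features: np.ndarray, train_y: np.ndarray,
                      query_features: np.ndarray, params: GPModelParams) -> np.ndarray:
    """Posterior predictive mean at query points given training data."""
    Xt = np.atleast_2d(np.asarray(train_features, float))
    Xq = np.atleast_2d(np.asarray(query_features, float))
    K = gp_gram(Xt, params)
    chol = _chol_with_jitter(K)
    if chol is None:
        raise np.linalg.LinAlgError("Gram matrix not positive definite")
    a = cho_solve(chol, np.asarray(train_y, float))
    xs = Xt / params.beta_weights
    qs = Xq / params.beta_weights
    d2 = (np.sum(qs * qs, axis=1)[:, None] + np.sum(xs * xs, axis=1)[None, :]
          - 2.0 * qs @ xs.T)
    np.clip(d2, 0.0, None, out=d2)
    Kq = params.sigma_f2 * np.exp(-0.5 * d2)
    return Kq @ a


# ---------------------------------------------------------------------------
# dataset bundle / composite likelihood
# ---------------------------------------------------------------------------

KINDS = ("fluorescence", "ordinal", "nominal", "fractional")


@dataclass
class Dataset:
    """A typed dataset plus its measurement model.

    data columns by kind:
      fluorescence: time_s, observable, value, sd
      ordinal:      time_s, observable, category (int)
      nominal:      cell_id, dose_ng_ml, outcome ('death'|'survival')
      fractional:   condition, dose_ng_ml, fraction, sd
    """

    kind: str
    data: pd.DataFrame
    model: object = None
    err: object = None  # misclassification model(s), ordinal only

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown dataset kind {self.kind!r}")


@dataclass
class DatasetBundle:
    datasets: list[Dataset] = field(default_factory=list)

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self):
        return len(self.datasets)


def composite_loglik(bundle: DatasetBundle,
                     trajectory: Trajectory | None = None,
                     nominal_features: np.ndarray | None = None,
                     fractional_features: np.ndarray | None = None) -> float:
    """Total log-likelihood of a mixed bundle: the sum over datasets.

    Any component at -inf makes the total -inf.  Feature matrices for nominal
    and fractional datasets are supplied by the caller (they depend on
    population simulations, not a single trajectory).
    """
    total = 0.0
    for ds in bundle:
        if ds.model is None:
            raise ValueError(f"dataset of kind {ds.kind!r} has no measurement model")
        if ds.kind == "fluorescence":
            pred = np.empty(len(ds.data))
            for obs, block in ds.data.groupby("observable"):
                y = normalize_signal(trajectory.observable(obs))
                pred[block.index.to_numpy()] = np.interp(
                    block["time_s"].to_numpy(), trajectory.times, y)
            total += fluorescence_loglik(pred, ds.data["value"].to_numpy(), ds.model)
        elif ds.kind == "ordinal":
            total += ordinal_dataset_loglik(trajectory, ds.data, ds.model, ds.err)
        elif ds.kind == "nominal":
            total += nominal_loglik(nominal_features,
                                    ds.data["outcome"].to_numpy(), ds.model)
        elif ds.kind == "fractional":
            total += gp_log_marginal_loglik(fractional_features,
                                            ds.data["fraction"].to_numpy(), ds.model)
        if not np.isfinite(total):
            return -np.inf
    return float(total)
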