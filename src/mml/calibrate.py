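"""Joint Bayesian calibration of mechanism and measurement parameters.

The posterior couples a mechanistic ODE model and one or more measurement
models through a composite likelihood.  Sampling uses a multi-chain
differential-evolution MCMC in the DREAM(ZS) family: proposal jumps are
scaled difference vectors of states drawn from a growing archive of past
states, with subspace (crossover) sampling whose selection probabilities
adapt during burn-in only, occasional gamma = 1 jumps for mode hopping, and
an optional snooker update (off by default).  Convergence is monitored by the
Gelman-Rubin potential-scale-reduction factor on the latter half of each
trace; a run stops when every free parameter's statistic is <= 1.2.

Default settings: 4 chains, nCR = 25 crossover levels, adaptive gamma with 8
levels, probability 0.10 of a gamma = 1 jump.

Mechanism rate parameters are sampled on log10 scale with independent normal
priors (sd 1.5) centered on the ground-truth vector; measurement-model
parameters carry the prior families described in :func:`PriorSpec` builders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "PriorSpec",
    "SamplerConfig",
    "ChainArchive",
    "CalibrationProblem",
    "log_prior",
    "sample_posterior",
    "gelman_rubin",
    "run_until_converged",
    "mechanism_rate_prior",
    "ordinal_slope_prior",
    "ordinal_theta_prior",
    "nominal_slope_prior",
    "nominal_weight_prior",
    "genotype_delta_prior",
    "extrinsic_variance_prior",
    "invgamma_from_cv_moments",
    "BIASED_ALPHA_PRIORS",
    "BIASED_THETA_PRIORS",
]


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Independent priors for the full free-parameter vector.

    Each entry pairs a frozen scipy distribution with optional hard support
    bounds that the sampler must respect even when the density itself has
    wider support (e.g. positive theta distances under a Cauchy prior).
    """

    names: list[str]
    dists: list
    lower: np.ndarray
    upper: np.ndarray

    @classmethod
    def from_blocks(cls, blocks: Sequence[tuple[str, object, float, float]]
                    ) -> "PriorSpec":
        names = [b[0] for b in blocks]
        dists = [b[1] for b in blocks]
        lower = np.array([b[2] for b in blocks], dtype=float)
        upper = np.array([b[3] for b in blocks], dtype=float)
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        return cls(names, dists, lower, upper)

    @property
    def dim(self) -> int:
        return len(self.names)

    def logpdf(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dim,):
            raise ValueError(
                f"parameter vector has {x.shape}, prior expects ({self.dim},)")
        if np.any(x < self.lower) or np.any(x > self.upper):
            return -np.inf
        total = 0.0
        for xi, d in zip(x, self.dists):
            total += d.logpdf(xi)
            if not np.isfinite(total):
                return -np.inf
        return float(total)

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        out = np.empty((n, self.dim))
        for j, d in enumerate(self.dists):
            draws = d.rvs(size=n, random_state=rng)
            # respect hard bounds by redrawing the (rare) violations
            bad = (draws < self.lower[j]) | (draws > self.upper[j])
            for _ in range(100):
                if not np.any(bad):
                    break
                draws[bad] = d.rvs(size=bad.sum(), random_state=rng)
                bad = (draws < self.lower[j]) | (draws > self.upper[j])
            out[:, j] = np.clip(draws, self.lower[j], self.upper[j])
        return out


def log_prior(params: np.ndarray, spec: PriorSpec) -> float:
    """Sum of independent log prior densities; -inf outside any support."""
    return spec.logpdf(params)


def mechanism_rate_prior(name: str, truth_log10: float, scale: float = 1.5):
    """Lognormal rate prior: normal on log10(rate), sd 1.5, centered at truth."""
    return (name, stats.norm(loc=truth_log10, scale=scale), -np.inf, np.inf)


def ordinal_slope_prior(name: str = "alpha"):
    """Exponential(scale 100) on the shared ordinal slope (> 0)."""
    return (name, stats.expon(scale=100.0), 0.0, np.inf)


def ordinal_theta_prior(name: str):
    """Exponential(scale 0.25) on a positive threshold distance."""
    return (name, stats.expon(scale=0.25), 0.0, np.inf)


def nominal_slope_prior(name: str = "nom_alpha"):
    return (name, stats.laplace(loc=0.0, scale=1.0), -np.inf, np.inf)


def nominal_weight_prior(name: str):
    """Laplace(0, 0.10) on the nominal intercept and feature weights."""
    return (name, stats.laplace(loc=0.0, scale=0.10), -np.inf, np.inf)


def genotype_delta_prior(name: str, location_log10: float, scale: float = 1.5):
    """Truncated lognormal on a DISC-formation multiplier, log10 scale.

    Upper truncation at 0 (wildtype): the mutant rate never exceeds wildtype.
    """
    a = (-np.inf - location_log10) / scale
    b = (0.0 - location_log10) / scale
    return (name, stats.truncnorm(a=-np.inf, b=b, loc=location_log10, scale=scale),
            -np.inf, 0.0)


def invgamma_from_cv_moments(mean_cv: float = 0.20, sd_cv: float = 0.015
                             ) -> tuple[float, float]:
    """Moment-match inverse-gamma (a, b) for the extrinsic variance v = cv^2.

    If v ~ InvGamma(a, b) then cv = sqrt(v) has E[cv] = sqrt(b) G(a-1/2)/G(a)
    and E[cv^2] = b/(a-1); a is solved so the cv coefficient of variation
    matches sd_cv/mean_cv, then b is set from the mean.
    """
    target = (sd_cv / mean_cv) ** 2

    def excess(a):
        # Var[cv]/E[cv]^2 as a function of a alone
        r = np.exp(special.gammaln(a - 0.5) - special.gammaln(a))
        return (1.0 / (a - 1.0)) / (r * r) - 1.0 - target

    a = optimize.brentq(excess, 1.5, 1e6)
    r = np.exp(special.gammaln(a - 0.5) - special.gammaln(a))
    b = (mean_cv / r) ** 2
    return a, b


def extrinsic_variance_prior(name: str = "extrinsic_var",
                             mean_cv: float = 0.20, sd_cv: float = 0.015):
    a, b = invgamma_from_cv_moments(mean_cv, sd_cv)
    return (name, stats.invgamma(a, scale=b), 0.0, np.inf)


#: biased prior variants for the ordinal slope alpha
BIASED_ALPHA_PRIORS = {
    "uniform": lambda name="alpha": (name, stats.uniform(0.0, 100.0), 0.0, 100.0),
    "cauchy_wide": lambda name="alpha": (name, stats.cauchy(50.0, 10.0), 0.0, np.inf),
    "cauchy_narrow": lambda name="alpha": (name, stats.cauchy(50.0, 1.0), 0.0, np.inf),
}

#: biased prior variants for the ordinal threshold distances theta_j
BIASED_THETA_PRIORS = {
    "uniform": lambda name: (name, stats.uniform(0.0, 1.0), 0.0, 1.0),
    "cauchy_wide": lambda name: (name, stats.cauchy(0.2, 0.05), 0.0, np.inf),
    "cauchy_narrow": lambda name: (name, stats.cauchy(0.2, 0.005), 0.0, np.inf),
}


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    n_chains: int = 4
    n_cr: int = 25
    adaptive_gamma: bool = True
    p_gamma_unity: float = 0.10
    gamma_levels: int = 8
    burn_in: int = 2000
    max_steps: int = 10000
    seed: int = 0
    archive_thin: int = 10
    snooker_prob: float = 0.0
    delta_pairs: int = 1
    jitter_scale: float = 1e-9
    check_interval: int = 1000
    gr_threshold: float = 1.2
    init_retries: int = 200

    def __post_init__(self):
        if self.n_chains < 3:
            raise ValueError("need >= 3 chains for convergence diagnostics")
        if self.burn_in >= self.max_steps:
            raise ValueError("burn_in must be < max_steps")


@dataclass
class ChainArchive:
    """Multi-chain trace of all free parameters with sampler bookkeeping."""

    names: list[str]
    traces: np.ndarray       # (n_chains, n_steps, dim)
    logposts: np.ndarray     # (n_chains, n_steps)
    past_states: np.ndarray  # ZS archive at termination
    burn_in: int
    converged: bool = False
    gelman_rubin: dict[str, float] = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.traces.shape[1]

    def posterior_samples(self, fraction: float = 0.5) -> np.ndarray:
        """Pooled samples from the latter ``fraction`` of every chain."""
        start = int(self.n_steps * (1.0 - fraction))
        return self.traces[:, start:, :].reshape(-1, len(self.names))

    def save(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("traces", data=self.traces)
            f.create_dataset("logposts", data=self.logposts)
            f.create_dataset("past_states", data=self.past_states)
            f.attrs["names"] = list(self.names)
            f.attrs["burn_in"] = self.burn_in
            f.attrs["converged"] = self.converged
            grp = f.create_group("gelman_rubin")
            for k, v in self.gelman_rubin.items():
                grp.attrs[k] = v

    @classmethod
    def load(cls, path: str) -> "ChainArchive":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                names=[str(n) for n in f.attrs["names"]],
                traces=f["traces"][...],
                logposts=f["logposts"][...],
                past_states=f["past_states"][...],
                burn_in=int(f.attrs["burn_in"]),
                converged=bool(f.attrs["converged"]),
                gelman_rubin=dict(f["gelman_rubin"].attrs),
            )


@dataclass
class CalibrationProblem:
    """Prior + likelihood contract handed to the sampler.

    ``loglik`` receives the full free-parameter vector and returns a float;
    infeasible simulations should surface as -inf, never as exceptions.
    """

    prior: PriorSpec
    loglik: Callable[[np.ndarray], float]

    def logpost(self, x: np.ndarray) -> float:
        lp = self.prior.logpdf(x)
        if not np.isfinite(lp):
            return -np.inf
        ll = self.loglik(x)
        return lp + ll if np.isfinite(ll) else -np.inf


class _DreamZS:
    """Differential-evolution MCMC state with a past-state archive."""

    def __init__(self, problem: CalibrationProblem, config: SamplerConfig):
        self.problem = problem
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        d = problem.prior.dim
        self.dim = d
        cfg = config
        # archive seeded from the prior; stored in a doubling buffer so
        # appends stay amortized O(1)
        m0 = max(10 * d, 2 * cfg.n_chains + 2)
        seed_states = problem.prior.sample(self.rng, m0)
        self._archive_buf = np.empty((max(4 * m0, 1024), d))
        self._archive_buf[:m0] = seed_states
        self._archive_len = m0
        # chain states must start feasible
        self.x = np.empty((cfg.n_chains, d))
        self.lp = np.full(cfg.n_chains, -np.inf)
        for i in range(cfg.n_chains):
            for _ in range(cfg.init_retries):
                cand = problem.prior.sample(self.rng, 1)[0]
                lp = problem.logpost(cand)
                if np.isfinite(lp):
                    self.x[i], self.lp[i] = cand, lp
                    break
            else:
                raise RuntimeError("could not initialize chains at finite posterior")
        # crossover bookkeeping
        self.cr_values = (np.arange(cfg.n_cr) + 1) / cfg.n_cr
        self.cr_prob = np.full(cfg.n_cr, 1.0 / cfg.n_cr)
        self._cr_count = np.zeros(cfg.n_cr)
        self._cr_dist = np.zeros(cfg.n_cr)
        self.step_count = 0
        self.trace_chunks: list[np.ndarray] = []
        self.lp_chunks: list[np.ndarray] = []

    @property
    def archive(self) -> np.ndarray:
        return self._archive_buf[:self._archive_len]

    def _archive_append(self, states: np.ndarray) -> None:
        need = self._archive_len + len(states)
        if need > len(self._archive_buf):
            grown = np.empty((max(2 * len(self._archive_buf), need), self.dim))
            grown[:self._archive_len] = self._archive_buf[:self._archive_len]
            self._archive_buf = grown
        self._archive_buf[self._archive_len:need] = states
        self._archive_len = need

    # -- proposal machinery -------------------------------------------------
    def _propose(self, i: int):
        cfg, rng = self.config, self.rng
        x = self.x[i]
        if rng.random() < cfg.snooker_prob and len(self.archive) >= 3:
            return self._snooker(x)
        m = rng.choice(cfg.n_cr, p=self.cr_prob)
        cr = self.cr_values[m]
        sub = rng.random(self.dim) < cr
        if not np.any(sub):
            sub[rng.integers(self.dim)] = True
        d_prime = int(sub.sum())
        rows = rng.choice(len(self.archive), size=2 * cfg.delta_pairs,
                          replace=False)
        diff = (self.archive[rows[:cfg.delta_pairs]].sum(axis=0)
                - self.archive[rows[cfg.delta_pairs:]].sum(axis=0))
        if rng.random() < cfg.p_gamma_unity:
            gamma = 1.0
        else:
            level = rng.integers(1, cfg.gamma_levels + 1)
            gamma = 2.38 / np.sqrt(2.0 * cfg.delta_pairs * d_prime * level)
        e = rng.uniform(-0.05, 0.05, size=self.dim)
        eps = rng.normal(0.0, cfg.jitter_scale, size=self.dim)
        prop = x.copy()
        prop[sub] = x[sub] + ((1 + e[sub]) * gamma * diff[sub]) + eps[sub]
        return prop, m, 0.0

    def _snooker(self, x: np.ndarray):
        rng = self.rng
        rows = rng.choice(len(self.archive), size=3, replace=False)
        z, za, zb = self.archive[rows]
        dvec = x - z
        norm2 = dvec @ dvec
        if norm2 == 0:
            return x.copy(), None, 0.0
        proj_a = (za @ dvec) / norm2 * dvec
        proj_b = (zb @ dvec) / norm2 * dvec
        gamma = rng.uniform(1.2, 2.2)
        prop = x + gamma * (proj_a - proj_b)
        # snooker Metropolis correction: (|prop-z|/|x-z|)^(d-1)
        num = np.linalg.norm(prop - z)
        den = np.linalg.norm(x - z)
        corr = (self.dim - 1) * (np.log(num) - np.log(den)) if den > 0 else 0.0
        return prop, None, corr

    # -- main loop ----------------------------------------------------------
    def run(self, n_steps: int) -> None:
        cfg = self.config
        d = self.dim
        chunk = np.empty((cfg.n_chains, n_steps, d))
        lp_chunk = np.empty((cfg.n_chains, n_steps))
        for s in range(n_steps):
            for i in range(cfg.n_chains):
                prop, m, corr = self._propose(i)
                lp_new = self.problem.logpost(prop)
                if np.log(self.rng.random()) < lp_new - self.lp[i] + corr:
                    if m is not None and self.step_count < cfg.burn_in:
                        std = np.std(self.x, axis=0)
                        std[std == 0] = 1.0
                        jump = (prop - self.x[i]) / std
                        self._cr_dist[m] += jump @ jump
                    self.x[i] = prop
                    self.lp[i] = lp_new
                if m is not None and self.step_count < cfg.burn_in:
                    self._cr_count[m] += 1
            # adapt crossover selection probabilities during burn-in only
            if (cfg.adaptive_gamma and self.step_count < cfg.burn_in
                    and self.step_count % 100 == 99 and self._cr_dist.sum() > 0):
                w = self._cr_dist / np.maximum(self._cr_count, 1)
                w = np.maximum(w, 1e-12)
                self.cr_prob = w / w.sum()
            if self.step_count % cfg.archive_thin == 0:
                self._archive_append(self.x)
            chunk[:, s, :] = self.x
            lp_chunk[:, s] = self.lp
            self.step_count += 1
        self.trace_chunks.append(chunk)
        self.lp_chunks.append(lp_chunk)

    def archive_result(self, converged: bool, gr: dict[str, float]) -> ChainArchive:
        traces = np.concatenate(self.trace_chunks, axis=1)
        lps = np.concatenate(self.lp_chunks, axis=1)
        return ChainArchive(names=list(self.problem.prior.names), traces=traces,
                            logposts=lps, past_states=self.archive,
                            burn_in=self.config.burn_in, converged=converged,
                            gelman_rubin=gr)


def gelman_rubin(traces: np.ndarray | ChainArchive,
                 fraction: float = 0.5) -> dict[str, float] | np.ndarray:
    """Potential-scale-reduction factor per parameter.

    Computed on the latter ``fraction`` of each chain: R = sqrt(((n-1)/n W +
    B/n) / W) with B the between- and W the within-chain variance.  A
    parameter with zero within-chain variance is degenerate and reported as
    NaN.  Accepts a raw (n_chains, n_steps, dim) array (returns an array) or
    a ChainArchive (returns a name-keyed dict).
    """
    if isinstance(traces, ChainArchive):
        vals = gelman_rubin(traces.traces, fraction)
        return dict(zip(traces.names, vals))
    traces = np.asarray(traces, dtype=float)
    n_chains, n_steps, dim = traces.shape
    if n_chains < 2:
        raise ValueError("need >= 2 chains")
    start = int(n_steps * (1.0 - fraction))
    seg = traces[:, start:, :]
    n = seg.shape[1]
    if n < 10:
        raise ValueError("need >= 10 retained samples per chain")
    chain_means = seg.mean(axis=1)                      # (chains, dim)
    W = seg.var(axis=1, ddof=1).mean(axis=0)            # (dim,)
    B = n * chain_means.var(axis=0, ddof=1)             # (dim,)
    out = np.full(dim, np.nan)
    ok = W > 0
    var_hat = (n - 1) / n * W[ok] + B[ok] / n
    out[ok] = np.sqrt(var_hat / W[ok])
    return out


def sample_posterior(problem: CalibrationProblem, config: SamplerConfig,
                     n_steps: int | None = None) -> ChainArchive:
    """Run the differential-evolution sampler for a fixed number of steps."""
    sampler = _DreamZS(problem, config)
    sampler.run(n_steps or config.max_steps)
    gr: dict[str, float] = {}
    converged = False
    if sampler.step_count >= 20:
        vals = gelman_rubin(np.concatenate(sampler.trace_chunks, axis=1))
        gr = dict(zip(problem.prior.names, vals))
        converged = bool(np.all(np.asarray(list(gr.values())) <= config.gr_threshold))
    return sampler.archive_result(converged, gr)


def run_until_converged(problem: CalibrationProblem,
                        config: SamplerConfig) -> ChainArchive:
    """Alternate sampling blocks and convergence checks.

    Stops once every free parameter's Gelman-Rubin statistic (latter 50% of
    the traces) is <= the threshold, or when ``max_steps`` is reached; an
    unconverged archive is returned flagged, never raised.
    """
    sampler = _DreamZS(problem, config)
    gr_vals = None
    while sampler.step_count < config.max_steps:
        block = min(config.check_interval, config.max_steps - sampler.step_count)
        sampler.run(block)
        if sampler.step_count <= config.burn_in:
            continue
        traces = np.concatenate(sampler.trace_chunks, axis=1)
        gr_vals = gelman_rubin(traces)
        if np.all(np.nan_to_num(gr_vals, nan=np.inf) <= config.gr_threshold):
            gr = dict(zip(problem.prior.names, gr_vals))
            return sampler.archive_result(True, gr)
    if gr_vals is None:
        traces = np.concatenate(sampler.trace_chunks, axis=1)
        gr_vals = gelman_rubin(traces)
    gr = dict(zip(problem.prior.names, gr_vals))
    return sampler.archive_result(False, gr)
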