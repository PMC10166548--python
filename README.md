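# mml — measurement-model calibration of apoptosis signaling dynamics

Most measurements in cell biology are not quantitative.  Immunoblots give
ordered categories, cell-fate assays give death/survival labels, viability
assays give fractions of a population — none of which map directly onto the
state variables of a mechanistic ODE model.  `mml` closes that gap with
explicit, probabilistic *measurement models*: functions that map latent model
variables to the probability of the values actually observed, with their own
free parameters inferred jointly with the mechanism by Bayesian MCMC.

The mechanistic substrate is a compact mass-action model of extrinsic
apoptosis execution (TRAIL ligand → DISC assembly → initiator caspase →
Bid truncation (tBID) → two sequential MOMP signal steps → effector caspase →
PARP cleavage), plus three non-apoptotic species that never interact with the
cascade, included to test whether data-driven measurement models can tell
drivers of cell fate from unrelated signals.

## Measurement models

For latent measurand `x(t, θ)` (e.g. normalized tBID):

* **Fluorescence** — i.i.d. Gaussian noise:
  `log L = Σ_i Σ_t −(ŷ_i(t) − y_i(t, θ))² / 2σ_i(t)²`.
* **Ordinal (cumulative model)** — `P(y ≥ c_j | x) = φ(α (x − β_j))` with
  shared slope α and monotone thresholds `β_j = β_{j−1} + θ_j`, `θ_j > 0`;
  category probabilities are differences of successive cumulative terms, and
  reported labels pass through a row-stochastic misclassification matrix
  (95% correct, 2.5% to each adjacent category).
* **Nominal (cell fate)** — `p(death) = φ(α(β + Σ_l β_l x_l))` on dynamic
  features of single-cell trajectories: time at maximum Bid-truncation rate,
  log maximum rate, and an unrelated non-apoptotic signal; observations are
  independent Bernoulli draws.
* **Fractional cell death** — zero-mean Gaussian-process regression with an
  automatic-relevance radial-basis kernel
  `κ(x_p, x_q) = σ_f² exp(−½ (x_p−x_q)ᵀ M (x_p−x_q))`, `M = diag(β)⁻²`,
  scored by the GP log marginal likelihood.

Mixed datasets multiply their likelihoods (log-likelihoods add).  Sampling
uses a 4-chain differential-evolution MCMC with a past-state archive
(DREAM(ZS) family: nCR = 25 adaptive crossover levels, 8 jump-size levels,
probability 0.10 of a γ = 1 mode-hopping jump), stopping when the
Gelman–Rubin statistic of every free parameter on the latter half of the
traces is ≤ 1.2.

## Worked example

Generate a synthetic ordinal tBID time course from the ground-truth model,
jointly calibrate five mechanism rates and the five-category ordinal
measurement model, and summarize posterior certainty:

```python
from mml.synthgen import default_ground_truth
from mml.workbench import ExperimentConfig, run_experiment

truth = default_ground_truth(reduced=True)
config = ExperimentConfig(
    name="demo", reduced=True,
    datasets=[{"type": "ordinal", "observables": ["tBID"],
               "interval_s": 300.0, "seed": 11}],
    free_rates=["kc0", "kf1", "kc1", "kc2", "kr1"],
    sampler={"burn_in": 2000, "max_steps": 30000, "check_interval": 2000},
    seed=5, n_draws=150)
result = run_experiment(config, truth=truth)
print("converged:", result.archive.converged)
print("max Gelman-Rubin:", max(result.archive.gelman_rubin.values()))
print("credible area:", round(result.area, 2))
print("truth contained:", result.truth_contained)
```

Output:

```
converged: True
max Gelman-Rubin: 1.132426035310194
credible area: 30.59
truth contained: True
```

All chains converged (every potential-scale-reduction factor ≤ 1.2); the 95%
posterior credible band of normalized tBID dynamics sums to ~31 width units
across the 100-point grid and contains the ground-truth trajectory — the
data-driven measurement model recovered an accurate mechanism from purely
ordinal data.

The same pipeline is scriptable from a shell:

```sh
mml generate --type ordinal --interval 60 --seed 1 --out ordinal.csv
mml calibrate --config run.yaml --seed 1 --archive chains.h5
mml summarize --archive chains.h5
```

## Layout

| module | contents |
| --- | --- |
| `mml.mechanism` | reaction network, LSODA simulation, population heterogeneity |
| `mml.measurement` | the four likelihood families and the composite likelihood |
| `mml.features` | finite-difference derivatives, fate features, critical points |
| `mml.synthgen` | ground-truth fixtures and ordinal/nominal/half-max generators |
| `mml.calibrate` | priors, DREAM(ZS)-style sampler, Gelman–Rubin control |
| `mml.posterior` | credible regions/areas, probability bands, weight posteriors, GP predictions |
| `mml.workbench` | experiment configs and generate→calibrate→summarize pipelines |

See `docs/methods.md` for modeling assumptions, parameter choices and known
limitations.
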