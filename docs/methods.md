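# Methods

## Mechanistic model

The apoptosis-execution network is a deliberately compact mass-action cascade
in copy-number units: TRAIL ligand binds receptor to form the death-inducing
signaling complex (DISC, rate `kc0`); initiator procaspase binds the DISC
reversibly (`kf1`/`kr1`) — the bound complex is the IC-DISC observable — and
is released in active form (`kc1`); active initiator caspase truncates Bid
(`kc2`); tBID drives two sequential MOMP "signal" activation steps
(`kc3`/`kc4`); the second MOMP signal activates effector caspase in a single
step (`kc5`), which cleaves PARP (`kc6`).  Three unrelated species USM1–3
form a feedback activation/inactivation loop (autocatalytic activation,
USM3-mediated inactivation, basal exchange) that shares no reaction with the
cascade; graph reachability from the ligand provably never touches them.

The ground-truth rate vector shipped in `mechanism._AEARM_PARAMS` was chosen
so that tBID under 50 ng/mL TRAIL shows snap-action delay dynamics: a flat
delay of roughly an hour, a sharp switch (inflection near 6700 s), and
saturation well before the end of the 0–20160 s window.  It is a documented
equivalent of the published model class, not a copy of any published
parameter table.  A reduced ligand→DISC→initiator-caspase→tBID cascade
(5 apoptotic rates + the USM loop) is provided for desk-scale calibrations.

Simulation uses LSODA (via `scipy.integrate.odeint`) with `rtol 1e-3`,
`atol 1e-6`, `mxstep 2^20` on a uniform 100-point grid over 0–20160 s;
off-grid times are obtained by linear interpolation.  The right-hand side is
numba-compiled (a pure-numpy fallback exists).  Integration failure or a
non-finite state raises a `SimulationError` that calibration code maps to
−∞ log-likelihood — an infeasible parameter vector never aborts a run.
Ligand dose converts at 60 copies per ng/mL (3000 copies ≙ 50 ng/mL).

Cell-to-cell variability: initial copy numbers of receptor, zymogens,
substrates and the USM pool are drawn from lognormals with the population
value as mean and coefficient of variation 0.20
(`μ = ln m − ½ln(1+cv²)`, `σ² = ln(1+cv²)`).  Dominant-negative FADD
genotypes are multipliers in (0, 1] on `kc0` only.

## Measurement models

**Ordinal.**  The cumulative (proportional-odds) model: the probability that
an ordinal reading reaches at least category `c_j` is
`φ(α (x − β_j))` with the standard logistic `φ`, a shared slope `α > 0`, and
monotone thresholds `β_j` on the normalized measurand scale parameterized by
positive distances `θ_j` (`β_0 = θ_0`, `β_j = β_{j−1} + θ_j`), so the
ordering constraint holds by construction for any admissible parameter
vector.  Writing the threshold *subtracted* from the measurand (rather than
an additive offset inside the logistic) is what makes monotone increasing
`β_j` consistent with decreasing cumulative probabilities and puts the
thresholds on the same [0, 1] scale as the measurand — the equal-fifths
parameterization (boundaries at every 0.2 of normalized tBID) is then
literally `θ_j = 0.2`.  Trajectories are normalized to [0, 1] by their own
maximum before entering any ordinal or fluorescence likelihood; a flat
trajectory cannot be normalized and is treated as infeasible.  Reported
labels are corrupted by a row-stochastic misclassification matrix: 95% on
the diagonal, 2.5% to each adjacent category (5% at the two ends).

**Nominal.**  Logistic model `p(death) = φ(α(β + Σ β_l x_l))` on three
features per cell: time at maximum tBID rate of change, log of that maximum
rate, and the unrelated USM2 level read at that time.  Features are affinely
mapped to ~[0, 1] (time by the window length; log-rate by `(ln r + 2)/12`,
spanning rates from ~0.14 to ~2·10⁴ copies/s; USM2 by the total pool size of
11,000 copies) so the Laplace(0, 0.10) weight priors act on comparable
scales.  Outcome labels carry no misclassification.

**Fractional cell death.**  A zero-mean GP with ARD radial-basis kernel over
critical-point features; observation noise enters the Gram diagonal only,
with per-point sd floored at 1e−3.  The Cholesky factorization first tries
zero jitter, then `1e−8·tr(K)/n` doubled up to three times before declaring
numerical failure (−∞).  The kernel uses the *difference* `x_p − x_q`; a
radial-basis kernel must be translation-invariant.  The GP mean is zero and
the data enter only through the marginal likelihood, which is standard GP
regression; using the observed values as the process mean for the same data
would make the likelihood degenerate.

**Composite.**  A mixed bundle's log-likelihood is the sum of its
components; any −∞ component makes the total −∞.

## Feature extraction

First derivatives use second-order central stencils (one-sided second-order
at the boundaries); second derivatives use fourth-order central stencils
(one-sided fourth-order 6-point stencils at the boundaries).  Relative
extrema are sign changes of the first derivative, inflections of the second;
derivative magnitudes below 1e−10 (normalized units) count as zero so float
noise never creates critical points, and boundary points are excluded.  Ties
in the maximum rate break to the earliest time.  The critical-point registry
is an append-only look-up table (capacity 10): new feature kinds get the
next column as they first appear in a calibration and re-seen kinds reuse
their column, so GP/logistic weights keep a fixed meaning for the whole run.
Absent features carry existence flag false and value 0.  The unrelated
readout is taken at the time of maximum Bid truncation.

## Synthetic data generation

All datasets are pure functions of (ground-truth config, seed).  Ordinal
category counts follow the effective-bit-resolution rule
`SNR = 20 log₁₀(range/(q₀.₉₅·rms))`, `EBR = (SNR−1.76)/6.02`,
`J ≤ 0.7·2^EBR` with `q₀.₉₅ = 1.6449`; `rms` is the rms of the *noise*
component, which is the reading under which the rule reduces to the standard
effective-resolution derivation for noisy analogue signals.  This gives 5
tBID and 4 cPARP categories for ~5% noise on a unit range; IC-DISC is fixed
at 4.  Measurement times are `t = kΔ, k = 1..⌊T/Δ⌋` by default ("interval"
counting: 112 points at 180 s, 336 at 60 s); "inclusive" counting adds
`t = 0`.

The fixture ground-truth measurement parameters are documented constants:
ordinal slope 25 with threshold distances 0.17/0.24/0.19/0.22 for tBID
(near, but deliberately not exactly, the even 0.2 spacing an analyst would
assume a priori) and similar near-even spacings for the 4-category models;
nominal slope 16, intercept 0.21, weights (−0.9, +0.6, 0) on the normalized
(time, log-rate, unrelated) features — late truncation favors survival, high
maximal rate favors death, the unrelated signal carries nothing.  Under
these constants the synthetic fate data show ~25% death at 10 ng/mL and
~75% at 50 ng/mL.  Nominal datasets record each cell's drawn initial
conditions (`ic_*` columns) so that calibration can pair every outcome with
the cell that produced it.  Half-max times come from linear interpolation of
the first upward crossing, rounded to the nearest 180 s.  A Gaussian-noise
emulator of normalized reporter time courses stands in for fluorescence
data in end-to-end tests.

## Priors

Mechanism rates are sampled on log10 scale with independent normal priors of
sd 1.5 centered on the ground-truth vector (order-of-magnitude rate
uncertainty).  Ordinal slope: exponential(scale 100); threshold distances:
exponential(scale 0.25); nominal slope: Laplace(0, 1); nominal intercept and
weights: Laplace(0, 0.10); genotype multipliers: normal on log10 with
locations 0 and −1, sd 1.5, truncated above at 0 (a mutant never exceeds
wildtype).  The extrinsic variance `v = cv²` has an inverse-gamma prior with
(a, b) moment-matched numerically so the induced `cv = √v` has mean 0.20 and
sd 0.015.  Biased variants for the ordinal block: uniform(0, 100) /
Cauchy(50, 10) / Cauchy(50, 1) for the slope and uniform(0, 1) /
Cauchy(0.2, 0.05) / Cauchy(0.2, 0.005) for the distances; hard support
bounds (`θ_j > 0`) are enforced regardless of the prior's nominal support.

## Sampler

Multi-chain differential-evolution MCMC with a past-state archive: 4 chains;
proposals jump along difference vectors of two archive rows, restricted to a
random crossover subspace (nCR = 25 levels whose selection probabilities
adapt during burn-in only, by accepted squared jump distance, and are frozen
afterwards to preserve detailed balance); jump scale
`γ = 2.38/√(2δ d′ m)` with `m` uniform on 1..8 levels, replaced by `γ = 1`
with probability 0.10 for mode hopping; small multiplicative (±5%) and
additive (sd 1e−9) noise break exact degeneracy.  The archive is seeded with
`max(10 d, 2·chains+2)` prior draws and appended every 10 steps.  A snooker
update is implemented but off by default — the archive-based difference
sampling is the core of the algorithm family and the snooker rate is not
among the documented settings.  Chain initialization redraws from the prior
until the posterior is finite (bounded retries).  Convergence control
computes the per-parameter potential-scale-reduction factor on the latter
50% of the traces between sampling blocks and stops when all are ≤ 1.2;
hitting the step budget returns an archive flagged unconverged rather than
raising.

## Posterior summaries

Credible regions re-simulate 1000 posterior draws (fewer, with replacement
and a warning, if the retained pool is smaller) and take pointwise
0.025/0.975 quantiles and the median over the 100-point grid; quantiles are
type-7 (numpy default) for bit-stable summaries.  The credible area is the
sum of band widths over the grid — the certainty metric, smaller meaning
more certain.  Normalization of predicted tBID uses each draw's own maximum.
Ordinal probability bands are per-category quantile envelopes over a grid of
normalized measurand values.  Effective nominal weights are the per-draw
products `α·β_l` (invariant to the joint sign flip that leaves all predicted
probabilities unchanged); features rank by median |weight|.  Population
feature clouds are summarized by Gaussian-KDE density fields
(Scott's-rule bandwidth) with a 0.05 density contour.  Fractional-cell-death
predictions evaluate the GP posterior mean conditioned on the training
conditions for each posterior draw and are clamped to [0, 1].

## Problem sizes

Desk-scale experiments use the reduced cascade, 2–5 free mechanism rates,
ordinal datasets of 13–336 points, fate datasets of 12–200 cells per dose,
and chains of 10³–4·10⁴ steps; these sizes were chosen so each experiment
completes in minutes on one CPU while preserving the statistical structure
(the same generators, likelihoods, priors and stopping rule as a full-scale
run).  The feature-selection experiment conditions on the ground-truth
mechanism: with the mechanism fixed, each cell's features are computable
once and the feature-relevance question becomes a fast posterior over the
five measurement parameters on all 400 observations.

## What the generators do and do not emulate

The synthetic data reproduce the statistical structure of the study
conditions — category counts from effective bit resolution, adjacent-category
misclassification, lognormal population heterogeneity, dose-dependent fate
frequencies, 3-minute temporal rounding — but not the artifacts of real
assays: no band-intensity saturation or background subtraction in
immunoblots, no photobleaching or spectral crosstalk in reporters, no
segmentation error in fate calls.  Passing tests therefore demonstrate
correctness of the inference machinery under the stated noise models, not
robustness to real-world measurement pathologies.

## Known limitations

* The ordinal likelihood treats repeated time points as independent given
  the trajectory; correlated blotting error across lanes is not modeled.
* The GP measurement model is homoscedastic per point and zero-mean; strong
  trends in fractional death outside the feature span extrapolate to 0.
* Desk-scale credible areas are not comparable in absolute value to
  full-scale ones (shorter chains, smaller datasets, fewer free rates);
  only orderings across datasets sharing a configuration are meaningful.
* The sampler is single-process; chains advance in lockstep within one
  interpreter.
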