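"""Synthetic dataset generation from ground-truth simulations.

Ordinal, nominal and half-max-time datasets are generated by pushing
ground-truth model simulations through fixture measurement models and drawing
categorical outcomes from the resulting probabilities.  The whole pipeline is
a pure function of (ground-truth config, seed).

The number of ordinal categories a technology can support follows from its
effective bit resolution: SNR = 20 log10(range / (q_0.95 * rms(noise))),
EBR = (SNR - 1.76) / 6.02, and the category count J is the largest integer
with J <= 0.7 * 2^EBR.  For the emulated reporter data this gives 5 tBID and
4 cPARP categories; IC-DISC is fixed at 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mml.features import extract_nominal_features, normalize_nominal_features
from mml.mechanism import (
    ReactionNetwork,
    SimulationGrid,
    Trajectory,
    build_aearm,
    build_reduced_cascade,
    sample_population,
    simulate,
)
from mml.measurement import (
    MisclassificationModel,
    NominalModelParams,
    OrdinalModelParams,
    nominal_prob,
    normalize_signal,
    ordinal_category_probs,
)

__all__ = [
    "ResolutionReport",
    "GroundTruthConfig",
    "default_ground_truth",
    "effective_resolution",
    "sampling_times",
    "generate_ordinal_dataset",
    "generate_nominal_dataset",
    "generate_half_max_times",
    "generate_fluorescence_dataset",
]

#: 0.95 quantile of the unit normal, as used in the effective-resolution rule
Q95 = 1.6449


@dataclass(frozen=True)
class ResolutionReport:
    snr_db: float
    ebr: float
    j_max: int


def effective_resolution(signal_range: float, noise_rms: float) -> ResolutionReport:
    """Category budget implied by a signal-to-noise ratio.

    ``noise_rms`` is the rms of the noise component (residual sd), scaled by
    the 0.95 unit-normal quantile to reflect a 0.10 two-sided adjacent-value
    misclassification rate.
    """
    if signal_range <= 0 or noise_rms <= 0:
        raise ValueError("signal range and noise rms must be positive")
    snr = 20.0 * math.log10(signal_range / (Q95 * noise_rms))
    ebr = (snr - 1.76) / 6.02
    j_max = math.floor(0.7 * 2.0 ** ebr)
    return ResolutionReport(snr_db=snr, ebr=ebr, j_max=j_max)


# ---------------------------------------------------------------------------
# ground truth fixtures
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthConfig:
    """Fixed "ground truth" used to synthesize every dataset.

    The ordinal fixture places 50% category boundaries near — but not exactly
    at — even intervals of the normalized signal (the 5-category tBID model
    uses threshold distances 0.17/0.24/0.19/0.22; the 4-category models use
    similar near-even spacings) with a shared slope of 25, so that an analyst's
    equal-interval assumption is approximately right but not exact.  The
    nominal fixture weights time-at-max-rate (negative: late truncation favors
    survival) and log-max-rate (positive), and gives the unrelated signal zero
    weight.  These are documented fixture constants, not published values.
    """

    network: ReactionNetwork
    ordinal_models: dict[str, OrdinalModelParams]
    nominal_model: NominalModelParams
    grid: SimulationGrid = field(default_factory=SimulationGrid)
    cv: float = 0.20
    doses: tuple[float, float] = (10.0, 50.0)
    n_per_dose: int = 200

    def simulate_truth(self, dose: float | None = None) -> Trajectory:
        initial = None
        if dose is not None:
            from mml.mechanism import ligand_copies
            initial = {"L": ligand_copies(dose)}
        return simulate(self.network, initial=initial, grid=self.grid)


def default_ground_truth(reduced: bool = False) -> GroundTruthConfig:
    network = build_reduced_cascade() if reduced else build_aearm()
    ordinal_models = {
        "tBID": OrdinalModelParams(
            alpha=25.0, theta_distances=np.array([0.17, 0.24, 0.19, 0.22])),
        "IC-DISC": OrdinalModelParams(
            alpha=25.0, theta_distances=np.array([0.22, 0.27, 0.24])),
    }
    if not reduced:
        ordinal_models["cPARP"] = OrdinalModelParams(
            alpha=25.0, theta_distances=np.array([0.23, 0.26, 0.24]))
    nominal_model = NominalModelParams(
        alpha=16.0, beta0=0.21, weights=np.array([-0.9, 0.6, 0.0]))
    return GroundTruthConfig(network=network, ordinal_models=ordinal_models,
                             nominal_model=nominal_model)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def sampling_times(interval_s: float, t_end: float = 20160.0,
                   counting: str = "interval") -> np.ndarray:
    """Measurement times t = k * interval.

    ``interval`` counting (default) runs k = 1..floor(T/interval) — 112 points
    at 180 s and 336 at 60 s over the 20160 s window; ``inclusive`` counting
    also includes t = 0.
    """
    if interval_s <= 0:
        raise ValueError("interval must be positive")
    k_max = int(math.floor(t_end / interval_s + 1e-9))
    if counting == "interval":
        ks = np.arange(1, k_max + 1)
    elif counting == "inclusive":
        ks = np.arange(0, k_max + 1)
    else:
        raise ValueError(f"unknown counting convention {counting!r}")
    return ks * interval_s


def generate_ordinal_dataset(
    truth: GroundTruthConfig,
    observables: tuple[str, ...] = ("tBID",),
    interval_s: float = 60.0,
    counting: str = "interval",
    seed: int = 0,
    misclassification: float = 0.05,
    dose: float | None = None,
    return_true: bool = False,
) -> pd.DataFrame:
    """Ordinal time courses drawn from the ground-truth measurement model.

    Ground-truth trajectories are normalized per observable, mapped to
    category probabilities by the fixture cumulative model, sampled, and then
    corrupted by the adjacent-category misclassification model.
    """
    rng = np.random.default_rng(seed)
    traj = truth.simulate_truth(dose)
    times = sampling_times(interval_s, truth.grid.t_end, counting)
    rows = []
    for obs in observables:
        params = truth.ordinal_models[obs]
        if params.n_categories < 2:
            raise ValueError("need at least two ordinal categories")
        y = normalize_signal(traj.observable(obs))
        x = np.interp(times, traj.times, y)
        probs = ordinal_category_probs(x, params)
        true_cats = np.array([rng.choice(params.n_categories, p=p) for p in probs])
        if misclassification > 0:
            err = MisclassificationModel.default(params.n_categories,
                                                 misclassification)
            reported = np.array([rng.choice(params.n_categories, p=err.matrix[c])
                                 for c in true_cats])
        else:
            reported = true_cats
        frame = pd.DataFrame({"time_s": times, "observable": obs,
                              "category": reported})
        if return_true:
            frame["true_category"] = true_cats
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def generate_nominal_dataset(
    truth: GroundTruthConfig,
    seed: int = 0,
    return_ensembles: bool = False,
):
    """Binary cell-fate records from two heterogeneous populations.

    For each dose, ``n_per_dose`` cells are simulated with lognormal
    initial-condition heterogeneity; the fixture logistic model maps each
    cell's (normalized) dynamic features to a death probability and the
    outcome is a Bernoulli draw.  Outcome labels carry no misclassification.
    """
    rng = np.random.default_rng(seed)
    rows = []
    ensembles = []
    cell_id = 0
    for dose in truth.doses:
        ens = sample_population(truth.network, n=truth.n_per_dose, cv=truth.cv,
                                dose=dose, seed=rng, grid=truth.grid)
        feats = np.array([
            normalize_nominal_features(extract_nominal_features(t))
            for t in ens.trajectories])
        p_death = nominal_prob(feats, truth.nominal_model)
        outcomes = np.where(rng.random(len(feats)) < p_death, "death", "survival")
        draws = ens.initial_condition_draws
        ic_cols = [c for c in draws.columns if c != "cell_id"]
        for j in range(len(feats)):
            row = {"cell_id": cell_id, "dose_ng_ml": dose, "outcome": outcomes[j]}
            # carry the known per-cell initial conditions: calibration pairs
            # each outcome with the cell that produced it
            for c in ic_cols:
                row[f"ic_{c}"] = draws[c].iloc[j]
            rows.append(row)
            cell_id += 1
        ensembles.append(ens)
    data = pd.DataFrame(rows)
    return (data, ensembles) if return_ensembles else data


def generate_half_max_times(
    truth: GroundTruthConfig,
    seed: int = 0,
    round_to_s: float = 180.0,
    observable: str = "tBID",
) -> pd.DataFrame:
    """Per-cell time of half-maximal signal, rounded to the nearest 3 minutes.

    The crossing time is found by linear interpolation between grid points;
    cells that never reach half their maximum are excluded.
    """
    rng = np.random.default_rng(seed)
    rows = []
    cell_id = 0
    for dose in truth.doses:
        ens = sample_population(truth.network, n=truth.n_per_dose, cv=truth.cv,
                                dose=dose, seed=rng, grid=truth.grid)
        for traj in ens.trajectories:
            t_half = half_max_time(traj.times, traj.observable(observable))
            if t_half is None:
                continue
            rows.append({"cell_id": cell_id, "dose_ng_ml": dose,
                         "t_half_s": round_to_s * round(t_half / round_to_s)})
            cell_id += 1
    return pd.DataFrame(rows)


def half_max_time(times: np.ndarray, y: np.ndarray) -> float | None:
    """First crossing of half the series maximum, by linear interpolation.

    Returns None when the series never reaches half its maximum (flat or
    all-zero trajectories).
    """
    y = np.asarray(y, dtype=float)
    if y.max() <= 0:
        return None
    half = 0.5 * y.max()
    above = np.nonzero(y >= half)[0]
    if above.size == 0:
        return None
    i = above[0]
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    y0, y1 = y[i - 1], y[i]
    return float(t0 + (half - y0) * (t1 - t0) / (y1 - y0))


def generate_fluorescence_dataset(
    truth: GroundTruthConfig,
    observables: tuple[str, ...] = ("tBID", "cPARP"),
    interval_s: float = 180.0,
    sd: float = 0.05,
    seed: int = 0,
    counting: str = "interval",
) -> pd.DataFrame:
    """Gaussian-noise emulation of normalized reporter time courses.

    Stands in for fluorescent caspase-reporter data in end-to-end tests:
    normalized ground-truth trajectories observed at fixed intervals with
    i.i.d. Gaussian noise of known sd.
    """
    rng = np.random.default_rng(seed)
    traj = truth.simulate_truth()
    times = sampling_times(interval_s, truth.grid.t_end, counting)
    rows = []
    for obs in observables:
        y = normalize_signal(traj.observable(obs))
        x = np.interp(times, traj.times, y)
        rows.append(pd.DataFrame({
            "time_s": times, "observable": obs,
            "value": x + rng.normal(0.0, sd, size=times.size), "sd": sd}))
    return pd.concat(rows, ignore_index=True)
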