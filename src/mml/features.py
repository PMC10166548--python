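"""Feature extraction from simulated signaling dynamics.

Measurement models for categorical and fractional cell-death data do not see
whole trajectories; they see low-dimensional summaries.  Two summaries are
used here:

* the nominal (cell-fate) feature triple — time at maximum Bid-truncation
  rate, log of that maximum rate, and the level of a designated unrelated
  non-apoptotic species read at that time;
* a critical-points representation — times/values of relative extrema and
  inflection points — with a bounded append-only look-up table so that feature
  columns keep a fixed meaning across an entire calibration.

Derivatives come from second-order (first derivative) and fourth-order
(second derivative) finite-difference stencils, one-sided at the boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from mml.mechanism import SimulationError, Trajectory

__all__ = [
    "NominalFeatureVector",
    "FeatureRegistry",
    "CriticalPointFeatures",
    "finite_diff_derivatives",
    "extract_nominal_features",
    "extract_critical_points",
    "normalize_nominal_features",
]

#: derivative magnitudes below this (normalized units) count as zero when
#: detecting sign changes, to avoid float-noise critical points
SIGN_EPS = 1e-10

#: default unrelated non-apoptotic readout for the nominal model
DEFAULT_UNRELATED_SPECIES = "USM2"


@dataclass(frozen=True)
class NominalFeatureVector:
    """Inputs to the logistic cell-fate model, one cell."""

    t_max_rate: float        # seconds
    log_max_rate: float      # ln(copies/s)
    unrelated_signal: float  # copies of the unrelated species at t_max_rate

    def as_array(self) -> np.ndarray:
        return np.array([self.t_max_rate, self.log_max_rate, self.unrelated_signal])


class FeatureRegistry:
    """Append-only look-up table mapping feature descriptors to columns.

    New critical-point kinds are appended as they first arise during a
    calibration; re-seen descriptors reuse their column, so the meaning of
    each GP/logistic weight is stable for the whole run.  Capacity is bounded
    (ten features).
    """

    def __init__(self, capacity: int = 10):
        self.capacity = capacity
        self._index: dict[str, int] = {}

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, descriptor: str) -> bool:
        return descriptor in self._index

    @property
    def descriptors(self) -> list[str]:
        return sorted(self._index, key=self._index.get)

    def register(self, descriptor: str) -> int:
        if descriptor in self._index:
            return self._index[descriptor]
        if len(self._index) >= self.capacity:
            raise OverflowError(
                f"feature registry full ({self.capacity}); cannot add {descriptor!r}")
        self._index[descriptor] = len(self._index)
        return self._index[descriptor]

    def column(self, descriptor: str) -> int:
        return self._index[descriptor]

    def to_json(self) -> str:
        return json.dumps({"capacity": self.capacity, "features": self.descriptors})

    @classmethod
    def from_json(cls, payload: str) -> "FeatureRegistry":
        d = json.loads(payload)
        reg = cls(capacity=d["capacity"])
        for name in d["features"]:
            reg.register(name)
        return reg


@dataclass
class CriticalPointFeatures:
    """Critical-point summary of one trajectory, aligned to a registry."""

    registry: FeatureRegistry
    values: dict[str, float] = field(default_factory=dict)
    exists: dict[str, bool] = field(default_factory=dict)

    def vector(self) -> np.ndarray:
        """Dense feature vector in registry column order; absent features are 0."""
        out = np.zeros(len(self.registry))
        for name, v in self.values.items():
            out[self.registry.column(name)] = v
        return out


# forward 6-point stencil for the second derivative, 4th-order accurate
_D2_FORWARD = np.array([45.0, -154.0, 214.0, -156.0, 61.0, -10.0]) / 12.0


def finite_diff_derivatives(values: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """First (2nd-order) and second (4th-order) finite-difference derivatives.

    Central stencils in the interior; one-sided stencils of matching order at
    the boundaries.  Requires at least 6 points (one-sided stencil width).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or y.size < 6:
        raise ValueError("need a 1-D series with at least 6 points")
    if dt <= 0:
        raise ValueError("dt must be positive")

    d1 = np.empty_like(y)
    d1[1:-1] = (y[2:] - y[:-2]) / (2 * dt)
    d1[0] = (-3 * y[0] + 4 * y[1] - y[2]) / (2 * dt)
    d1[-1] = (3 * y[-1] - 4 * y[-2] + y[-3]) / (2 * dt)

    d2 = np.empty_like(y)
    d2[2:-2] = (-y[:-4] + 16 * y[1:-3] - 30 * y[2:-2] + 16 * y[3:-1] - y[4:]) / (12 * dt * dt)
    h2 = dt * dt
    d2[0] = _D2_FORWARD @ y[:6] / h2
    d2[1] = _D2_FORWARD @ y[1:7] / h2 if y.size >= 7 else d2[2]
    d2[-1] = _D2_FORWARD @ y[-6:][::-1] / h2
    d2[-2] = _D2_FORWARD @ y[-7:-1][::-1] / h2 if y.size >= 7 else d2[-3]
    return d1, d2


def extract_nominal_features(
    trajectory: Trajectory,
    unrelated_species: str = DEFAULT_UNRELATED_SPECIES,
    observable: str = "tBID",
) -> NominalFeatureVector:
    """Cell-fate features from one trajectory.

    The maximum rate of change of the observable is located on the
    finite-difference first derivative (earliest time breaks ties); a flat
    trajectory has no defined log-rate and signals an infeasible simulation.
    """
    y = trajectory.observable(observable)
    d1, _ = finite_diff_derivatives(y, trajectory.grid.dt)
    i = int(np.argmax(d1))  # argmax returns the first maximizer
    max_rate = d1[i]
    if max_rate <= SIGN_EPS:
        raise SimulationError(f"flat {observable} trajectory: max rate not positive")
    t = trajectory.times[i]
    unrelated = trajectory.series(unrelated_species)[i]
    return NominalFeatureVector(t_max_rate=float(t),
                                log_max_rate=float(np.log(max_rate)),
                                unrelated_signal=float(unrelated))


# Affine ranges mapping raw nominal features onto ~[0, 1] so that logistic
# weights with Laplace(0, 0.1) priors act on comparable scales:
# time / t_end; (ln rate + 2) / 12 spans rates from ~0.14 to ~2e4 copies/s;
# unrelated signal / total copies of the USM pool.
NOMINAL_FEATURE_SCALE = {
    "t_max_rate": 20160.0,
    "log_max_rate": 12.0,
    "log_max_rate_offset": 2.0,
    "unrelated_signal": 11000.0,
}


def normalize_nominal_features(fv: NominalFeatureVector) -> np.ndarray:
    s = NOMINAL_FEATURE_SCALE
    return np.array([
        fv.t_max_rate / s["t_max_rate"],
        (fv.log_max_rate + s["log_max_rate_offset"]) / s["log_max_rate"],
        fv.unrelated_signal / s["unrelated_signal"],
    ])


def _sign_changes(values: np.ndarray) -> list[tuple[int, int]]:
    """(index, new_sign) pairs where the series changes sign, interior only."""
    v = np.where(np.abs(values) < SIGN_EPS, 0.0, values)
    out = []
    prev_sign = 0
    for i in range(1, len(v) - 1):
        s = int(np.sign(v[i]))
        if s == 0:
            continue
        if prev_sign != 0 and s != prev_sign:
            out.append((i, s))
        prev_sign = s
    return out


def extract_critical_points(
    trajectory: Trajectory,
    registry: FeatureRegistry,
    observable: str = "tBID",
) -> CriticalPointFeatures:
    """Critical-points representation of one trajectory.

    Relative maxima/minima come from sign changes of the first derivative and
    inflections from sign changes of the second; boundary points are excluded.
    Each feature kind found is registered (idempotently) in the look-up table;
    kinds absent from this trajectory keep existence flag False and value 0 in
    the dense vector.  Times are normalized by the grid end, values by the
    trajectory's own maximum.
    """
    y = trajectory.observable(observable)
    norm = y.max()
    yn = y / norm if norm > 0 else y
    dt = trajectory.grid.dt
    d1, d2 = finite_diff_derivatives(yn, dt)
    t = trajectory.times

    feats = CriticalPointFeatures(registry=registry)

    def put(name: str, value: float):
        registry.register(name)
        feats.values[name] = float(value)
        feats.exists[name] = True

    # always defined: maximum truncation rate of the (normalized) observable
    put("max_rate", d1.max())

    crossings_d1 = _sign_changes(d1)
    maxima = [i for i, s in crossings_d1 if s < 0]
    minima = [i for i, s in crossings_d1 if s > 0]
    inflections = [i for i, _ in _sign_changes(d2)]

    if maxima:
        i = maxima[0]
        put("rel_max_time", t[i] / t[-1])
        put("rel_max_value", yn[i])
    else:
        feats.exists["rel_max_time"] = feats.exists["rel_max_value"] = False
    if minima:
        i = minima[0]
        put("rel_min_time", t[i] / t[-1])
        put("rel_min_value", yn[i])
    else:
        feats.exists["rel_min_time"] = feats.exists["rel_min_value"] = False
    if inflections:
        i = inflections[0]
        put("inflection_time", t[i] / t[-1])
        put("inflection_value", yn[i])
        put("inflection_rate", d1[i])
    else:
        feats.exists["inflection_time"] = False
        feats.exists["inflection_value"] = False
        feats.exists["inflection_rate"] = False
    return feats
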