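"""Abridged extrinsic apoptosis reaction network and ODE simulation.

The network is a compact mass-action cascade from death-ligand binding to PARP
cleavage: ligand + receptor form the death-inducing signaling complex (DISC);
initiator caspase binds the DISC (the IC-DISC observable) and is released in
active form; active initiator caspase truncates Bid; truncated Bid (tBID)
triggers two sequential mitochondrial outer-membrane-permeabilization (MOMP)
"signal" activation steps; the second MOMP signal activates effector caspase in
a single step, which cleaves PARP.  Three additional species (USM1-3) form a
feedback activation/inactivation loop that never interacts with the apoptotic
cascade; they exist to test whether a data-driven measurement model can tell
drivers of cell fate from unrelated signals.

All kinetics are elementary mass action with copy-number units.  Rate
parameters span orders of magnitude, so calibration works on log10-transformed
rates; the simulator consumes linear-scale values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import odeint

try:  # compiled mass-action right-hand side; pure-numpy fallback below
    import numba

    @numba.njit(cache=False)
    def _rhs_compiled(y, t, k, i1, i2, has2, stoich):
        rates = np.empty(k.size)
        for r in range(k.size):
            v = k[r] * y[i1[r]]
            if has2[r]:
                v *= y[i2[r]]
            rates[r] = v
        return stoich @ rates

except ImportError:  # pragma: no cover - numba is a declared dependency
    _rhs_compiled = None

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "GenotypeModifier",
    "SimulationGrid",
    "Trajectory",
    "PopulationEnsemble",
    "SimulationError",
    "build_aearm",
    "build_reduced_cascade",
    "simulate",
    "sample_population",
    "lognormal_params",
    "ligand_copies",
]

#: copy numbers per (ng/mL) of TRAIL; 50 ng/mL corresponds to 3000 molecules.
LIGAND_COPIES_PER_NG_ML = 60.0

#: species whose initial copy numbers vary cell-to-cell by default; the USM
#: pool varies too, so the unrelated signal fluctuates across cells without
#: carrying any fate information
DEFAULT_HETEROGENEOUS = ("R", "C8", "Bid", "M1", "M2", "C3", "PARP",
                         "USM1", "USM2", "USM3")


class SimulationError(RuntimeError):
    """Raised when integration fails; callers map this to -inf log-likelihood."""


@dataclass(frozen=True)
class Reaction:
    """One irreversible mass-action reaction (order <= 2)."""

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: str

    def __post_init__(self):
        if not 1 <= len(self.reactants) <= 2:
            raise ValueError("mass-action order must be 1 or 2")


@dataclass(frozen=True)
class SimulationGrid:
    """Uniform time grid; defaults match the fluorescence time-course layout."""

    t_start: float = 0.0
    t_end: float = 20160.0
    n_points: int = 100

    def __post_init__(self):
        if self.t_end <= self.t_start or self.n_points < 2:
            raise ValueError("grid must be strictly increasing with >= 2 points")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(self.t_start, self.t_end, self.n_points)

    @property
    def dt(self) -> float:
        return (self.t_end - self.t_start) / (self.n_points - 1)


@dataclass
class ReactionNetwork:
    species: list[str]
    reactions: list[Reaction]
    parameters: dict[str, float]
    initial_conditions: dict[str, float]
    observables: dict[str, tuple[str, ...]] = field(default_factory=dict)
    heterogeneous_species: tuple[str, ...] = ()

    def __post_init__(self):
        sp = set(self.species)
        for rxn in self.reactions:
            if rxn.rate_constant not in self.parameters:
                raise ValueError(f"rate constant {rxn.rate_constant!r} missing")
            for s in rxn.reactants + rxn.products:
                if s not in sp:
                    raise ValueError(f"unknown species {s!r}")
        for s, v in self.initial_conditions.items():
            if v < 0:
                raise ValueError(f"negative initial condition for {s!r}")
        self._compiled = None

    # --- structure -------------------------------------------------------
    def reachable_from(self, source: str) -> set[str]:
        """Species reachable from `source` through shared reactions."""
        reached = {source}
        frontier = True
        while frontier:
            frontier = False
            for rxn in self.reactions:
                members = set(rxn.reactants) | set(rxn.products)
                if members & reached and not members <= reached:
                    reached |= members
                    frontier = True
        return reached

    def observable_species(self, name: str) -> tuple[str, ...]:
        return self.observables[name]

    # --- compilation to index arrays ------------------------------------
    def _compile(self):
        if self._compiled is None:
            index = {s: i for i, s in enumerate(self.species)}
            n_rxn = len(self.reactions)
            i1 = np.empty(n_rxn, dtype=np.intp)
            i2 = np.full(n_rxn, -1, dtype=np.intp)
            stoich = np.zeros((len(self.species), n_rxn))
            for r, rxn in enumerate(self.reactions):
                i1[r] = index[rxn.reactants[0]]
                if len(rxn.reactants) == 2:
                    i2[r] = index[rxn.reactants[1]]
                for s in rxn.reactants:
                    stoich[index[s], r] -= 1
                for s in rxn.products:
                    stoich[index[s], r] += 1
            has2 = i2 >= 0
            knames = [rxn.rate_constant for rxn in self.reactions]
            self._compiled = (i1, i2, has2, stoich, knames, index)
        return self._compiled

    def rate_vector(self, overrides: dict[str, float] | None = None) -> np.ndarray:
        params = self.parameters if not overrides else {**self.parameters, **overrides}
        knames = self._compile()[4]
        k = np.array([params[name] for name in knames], dtype=float)
        if np.any(k < 0) or not np.all(np.isfinite(k)):
            raise ValueError("rate constants must be finite and nonnegative")
        return k

    def initial_vector(self, overrides: dict[str, float] | None = None) -> np.ndarray:
        ic = self.initial_conditions if not overrides else {
            **self.initial_conditions, **overrides}
        y0 = np.array([ic.get(s, 0.0) for s in self.species], dtype=float)
        if np.any(y0 < 0):
            raise ValueError("initial conditions must be nonnegative")
        return y0

    # --- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "species": list(self.species),
            "reactions": [
                {"reactants": list(r.reactants), "products": list(r.products),
                 "rate_constant": r.rate_constant}
                for r in self.reactions
            ],
            "parameters": dict(self.parameters),
            "initial_conditions": dict(self.initial_conditions),
            "observables": {k: list(v) for k, v in self.observables.items()},
            "heterogeneous_species": list(self.heterogeneous_species),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionNetwork":
        return cls(
            species=list(d["species"]),
            reactions=[Reaction(tuple(r["reactants"]), tuple(r["products"]),
                                r["rate_constant"]) for r in d["reactions"]],
            parameters=dict(d["parameters"]),
            initial_conditions=dict(d["initial_conditions"]),
            observables={k: tuple(v) for k, v in d.get("observables", {}).items()},
            heterogeneous_species=tuple(d.get("heterogeneous_species", ())),
        )


@dataclass(frozen=True)
class GenotypeModifier:
    """Multiplier in (0, 1] on the DISC-formation rate kc0.

    Models graded dominant-negative FADD expression: diminished DISC formation
    relative to wildtype.  Multiplier 1 is wildtype.
    """

    multiplier: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.multiplier <= 1.0:
            raise ValueError("genotype multiplier must be in (0, 1]")

    def apply(self, network: ReactionNetwork) -> dict[str, float]:
        params = dict(network.parameters)
        params["kc0"] = params["kc0"] * self.multiplier
        return params


@dataclass
class Trajectory:
    """Species time courses on a simulation grid."""

    grid: SimulationGrid
    species: list[str]
    values: np.ndarray  # (n_points, n_species)
    observables: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if self.values.shape != (self.grid.n_points, len(self.species)):
            raise ValueError("values shape does not match grid/species")

    @property
    def times(self) -> np.ndarray:
        return self.grid.times

    def series(self, species: str) -> np.ndarray:
        return self.values[:, self.species.index(species)]

    def observable(self, name: str) -> np.ndarray:
        members = self.observables.get(name, (name,))
        cols = [self.species.index(s) for s in members]
        return self.values[:, cols].sum(axis=1)

    def at(self, name: str, t: np.ndarray | float) -> np.ndarray:
        """Linear interpolation of an observable at off-grid times."""
        return np.interp(t, self.times, self.observable(name))

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for i, s in enumerate(self.species):
            frames.append(pd.DataFrame(
                {"time_s": self.times, "species": s, "value": self.values[:, i]}))
        return pd.concat(frames, ignore_index=True)


@dataclass
class PopulationEnsemble:
    """Heterogeneous population of single-cell trajectories at one ligand dose."""

    trajectories: list[Trajectory]
    initial_condition_draws: pd.DataFrame
    ligand_dose: float

    def __len__(self) -> int:
        return len(self.trajectories)


# ---------------------------------------------------------------------------
# network definitions
# ---------------------------------------------------------------------------

def ligand_copies(dose_ng_ml: float) -> float:
    """TRAIL dose in ng/mL -> ligand copy number per cell."""
    return dose_ng_ml * LIGAND_COPIES_PER_NG_ML


# Ground-truth rate vector for the shipped network.  Tuned so tBID under
# 50 ng/mL shows snap-action delay dynamics (sigmoid, single inflection near
# the middle of the 0-20160 s window); an equivalent of, not a copy of, any
# published parameterization.
_AEARM_PARAMS = {
    "kc0": 1.0e-6,   # L + R -> DISC
    "kf1": 1.0e-6,   # DISC + C8 -> DISC:C8
    "kr1": 1.0e-3,   # DISC:C8 -> DISC + C8
    "kc1": 1.0e-3,   # DISC:C8 -> DISC + C8a
    "kc2": 3.0e-8,   # C8a + Bid -> C8a + tBID
    "kc3": 3.0e-7,   # tBID + M1 -> tBID + M1a     (MOMP signal step 1)
    "kc4": 3.0e-7,   # M1a + M2 -> M1a + M2a       (MOMP signal step 2)
    "kc5": 1.0e-6,   # M2a + C3 -> M2a + C3a       (single effector step)
    "kc6": 3.0e-8,   # C3a + PARP -> C3a + cPARP
    "ku1": 1.0e-6,   # USM1 + USM2 -> 2 USM2       (autocatalytic activation)
    "ku2": 1.0e-6,   # USM2 + USM3 -> USM1 + USM3  (USM3-mediated inactivation)
    "ku3": 1.0e-4,   # USM1 -> USM2                (basal activation)
    "ku4": 1.0e-4,   # USM2 -> USM1                (basal inactivation)
}

_AEARM_INITIAL = {
    "L": ligand_copies(50.0),
    "R": 1000.0,
    "DISC": 0.0,
    "C8": 10000.0,
    "DISC_C8": 0.0,
    "C8a": 0.0,
    "Bid": 40000.0,
    "tBID": 0.0,
    "M1": 20000.0,
    "M1a": 0.0,
    "M2": 20000.0,
    "M2a": 0.0,
    "C3": 10000.0,
    "C3a": 0.0,
    "PARP": 100000.0,
    "cPARP": 0.0,
    "USM1": 10000.0,
    "USM2": 1000.0,
    "USM3": 2000.0,
}


def build_aearm() -> ReactionNetwork:
    """Construct the abridged extrinsic apoptosis network.

    Observables: ``tBID`` (truncated Bid), ``cPARP`` (cleaved PARP) and
    ``IC-DISC`` (initiator caspase bound to the DISC).  USM1-3 are the
    unrelated non-apoptotic species; graph reachability from the ligand never
    touches them.
    """
    species = list(_AEARM_INITIAL)
    reactions = [
        Reaction(("L", "R"), ("DISC",), "kc0"),
        Reaction(("DISC", "C8"), ("DISC_C8",), "kf1"),
        Reaction(("DISC_C8",), ("DISC", "C8"), "kr1"),
        Reaction(("DISC_C8",), ("DISC", "C8a"), "kc1"),
        Reaction(("C8a", "Bid"), ("C8a", "tBID"), "kc2"),
        Reaction(("tBID", "M1"), ("tBID", "M1a"), "kc3"),
        Reaction(("M1a", "M2"), ("M1a", "M2a"), "kc4"),
        Reaction(("M2a", "C3"), ("M2a", "C3a"), "kc5"),
        Reaction(("C3a", "PARP"), ("C3a", "cPARP"), "kc6"),
        Reaction(("USM1", "USM2"), ("USM2", "USM2"), "ku1"),
        Reaction(("USM2", "USM3"), ("USM1", "USM3"), "ku2"),
        Reaction(("USM1",), ("USM2",), "ku3"),
        Reaction(("USM2",), ("USM1",), "ku4"),
    ]
    return ReactionNetwork(
        species=species,
        reactions=reactions,
        parameters=dict(_AEARM_PARAMS),
        initial_conditions=dict(_AEARM_INITIAL),
        observables={
            "tBID": ("tBID",),
            "cPARP": ("cPARP",),
            "IC-DISC": ("DISC_C8",),
        },
        heterogeneous_species=DEFAULT_HETEROGENEOUS,
    )


def build_reduced_cascade() -> ReactionNetwork:
    """Small ligand->DISC->initiator-caspase->tBID cascade with the USM loop.

    Five apoptotic rate parameters; used for desk-scale calibrations where
    per-step simulation cost matters.
    """
    initial = {
        "L": ligand_copies(50.0), "R": 1000.0, "DISC": 0.0,
        "C8": 10000.0, "DISC_C8": 0.0, "C8a": 0.0,
        "Bid": 40000.0, "tBID": 0.0,
        "USM1": 10000.0, "USM2": 1000.0, "USM3": 2000.0,
    }
    reactions = [
        Reaction(("L", "R"), ("DISC",), "kc0"),
        Reaction(("DISC", "C8"), ("DISC_C8",), "kf1"),
        Reaction(("DISC_C8",), ("DISC", "C8"), "kr1"),
        Reaction(("DISC_C8",), ("DISC", "C8a"), "kc1"),
        Reaction(("C8a", "Bid"), ("C8a", "tBID"), "kc2"),
        Reaction(("USM1", "USM2"), ("USM2", "USM2"), "ku1"),
        Reaction(("USM2", "USM3"), ("USM1", "USM3"), "ku2"),
        Reaction(("USM1",), ("USM2",), "ku3"),
        Reaction(("USM2",), ("USM1",), "ku4"),
    ]
    params = {k: _AEARM_PARAMS[k] for k in
              ("kc0", "kf1", "kr1", "kc1", "kc2", "ku1", "ku2", "ku3", "ku4")}
    return ReactionNetwork(
        species=list(initial),
        reactions=reactions,
        parameters=params,
        initial_conditions=initial,
        observables={"tBID": ("tBID",), "IC-DISC": ("DISC_C8",)},
        heterogeneous_species=("R", "C8", "Bid", "USM1", "USM2", "USM3"),
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(
    network: ReactionNetwork,
    params: dict[str, float] | None = None,
    initial: dict[str, float] | None = None,
    grid: SimulationGrid | None = None,
    rtol: float = 1e-3,
    atol: float = 1e-6,
    mxstep: int = 2 ** 20,
) -> Trajectory:
    """Deterministic LSODA integration of the mass-action ODEs on the grid.

    Raises :class:`SimulationError` on integrator failure or non-finite state;
    calibration code maps that to an infeasible parameter vector (-inf
    log-likelihood) rather than aborting.
    """
    grid = grid or SimulationGrid()
    i1, i2, has2, stoich, _, _ = network._compile()
    k = network.rate_vector(params)
    y0 = network.initial_vector(initial)

    if _rhs_compiled is not None:
        rhs = _rhs_compiled
        rhs_args = (k, i1.astype(np.int64), i2.astype(np.int64), has2,
                    np.ascontiguousarray(stoich))
    else:
        def rhs(y, _t):
            rates = k * y[i1]
            rates[has2] *= y[i2[has2]]
            return stoich @ rates
        rhs_args = ()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol, info = odeint(rhs, y0, grid.times, args=rhs_args, rtol=rtol,
                           atol=atol, mxstep=mxstep, full_output=True)
    if info["message"] != "Integration successful." or not np.all(np.isfinite(sol)):
        raise SimulationError(f"integration failed: {info['message']}")
    # integrator tolerance can leave tiny negative excursions
    np.clip(sol, 0.0, None, out=sol)
    return Trajectory(grid=grid, species=list(network.species), values=sol,
                      observables=dict(network.observables))


def lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of ln X for a lognormal with given mean and CV.

    mu = ln m - 0.5*ln(1+cv^2), sigma^2 = ln(1+cv^2); moment matching so the
    draw mean equals the population-average copy number exactly.
    """
    s2 = np.log1p(cv * cv)
    return np.log(mean) - 0.5 * s2, np.sqrt(s2)


def sample_population(
    network: ReactionNetwork,
    n: int,
    cv: float = 0.20,
    dose: float = 50.0,
    seed: int | np.random.Generator = 0,
    grid: SimulationGrid | None = None,
    params: dict[str, float] | None = None,
    species: tuple[str, ...] | None = None,
    simulate_cells: bool = True,
) -> PopulationEnsemble:
    """Simulate a heterogeneous population at one TRAIL dose.

    Initial copy numbers of the designated heterogeneous species are drawn
    from lognormals whose mean equals the population value and whose
    coefficient of variation is ``cv`` (cv=0 collapses to the means).  The
    ligand initial condition is set from the dose.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if cv < 0:
        raise ValueError("cv must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    het = species if species is not None else network.heterogeneous_species
    draws = {}
    for s in het:
        mean = network.initial_conditions[s]
        if cv == 0 or mean == 0:
            draws[s] = np.full(n, mean)
        else:
            mu, sigma = lognormal_params(mean, cv)
            draws[s] = rng.lognormal(mu, sigma, size=n)
    table = pd.DataFrame(draws)
    table.insert(0, "cell_id", np.arange(n))
    trajectories = []
    if simulate_cells:
        for i in range(n):
            overrides = {s: draws[s][i] for s in het}
            overrides["L"] = ligand_copies(dose)
            trajectories.append(simulate(network, params=params,
                                         initial=overrides, grid=grid))
    return PopulationEnsemble(trajectories=trajectories,
                              initial_condition_draws=table,
                              ligand_dose=dose)
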