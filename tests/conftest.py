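import numpy as np
import pytest

from mml.mechanism import SimulationGrid, Trajectory, build_aearm, build_reduced_cascade, simulate
from mml.synthgen import default_ground_truth


@pytest.fixture(scope="session")
def aearm():
    return build_aearm()


@pytest.fixture(scope="session")
def reduced_net():
    return build_reduced_cascade()


@pytest.fixture(scope="session")
def truth_reduced():
    return default_ground_truth(reduced=True)


@pytest.fixture(scope="session")
def truth_trajectory(aearm):
    """Ground-truth simulation of the full network at 50 ng/mL."""
    return simulate(aearm)


def make_trajectory(values: np.ndarray, species: str = "tBID",
                    grid: SimulationGrid | None = None) -> Trajectory:
    """Single-species trajectory on the standard grid, for toy inputs."""
    grid = grid or SimulationGrid()
    vals = np.asarray(values, dtype=float)[:, None]
    return Trajectory(grid=grid, species=[species], values=vals,
                      observables={species: (species,)})
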