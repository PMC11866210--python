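"""Shared fixtures: small deterministic trajectories and toy models."""
import numpy as np
import pytest

from advib.trajectory import Trajectory
from advib.synthetic import glycinate_toy


@pytest.fixture(scope="session")
def toy_single():
    """9-atom glycinate harmonic toy with the default mode placement."""
    return glycinate_toy()


@pytest.fixture(scope="session")
def toy_pair():
    """Glide-symmetric 18-atom pair layout."""
    return glycinate_toy(layout="glide_pair")


@pytest.fixture()
def oscillating_traj():
    """One H atom oscillating along z at an exact integer number of periods."""
    n, dt = 4096, 0.25
    t = dt * np.arange(n)
    period = n * dt / 64           # 64 whole periods in the window
    nu = 1.0 / period
    z = 0.1 * np.cos(2 * np.pi * nu * t)
    pos = np.zeros((n, 1, 3))
    pos[:, 0, 2] = z
    vel = np.zeros((n, 1, 3))
    vel[:, 0, 2] = -0.1 * 2 * np.pi * nu * np.sin(2 * np.pi * nu * t)
    return Trajectory(species=["H"], positions=pos, velocities=vel, timestep=dt)


def make_static_traj(n_frames=10, cell=None):
    pos = np.tile(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 2.0]]), (n_frames, 1, 1))
    return Trajectory(species=["O", "O"], positions=pos, timestep=1.0, cell=cell)
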