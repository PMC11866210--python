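"""Local-mode basis construction, s-vector projection, per-mode spectra."""
import numpy as np
import pytest

from advib.errors import PreconditionError, TopologyError
from advib.localmodes import (Topology, bond_stretch_series,
                              build_local_mode_basis, glycinate_topology,
                              local_mode_spectra, primitive_s_vectors,
                              primitive_value, project_velocities)
from advib.synthetic import glycinate_geometry, glycinate_toy, normal_mode_trajectory
from advib.trajectory import Trajectory


EXPECTED_NAMES = {
    "nu_s(NH2)", "nu_a(NH2)", "nu_s(CH2)", "nu_a(CH2)", "nu_s(CO2)",
    "nu_a(CO2)", "nu(CN)", "nu(CC)", "tau(CN)", "tau(CC)", "delta(NH2)",
    "delta(CH2)", "delta(CO2)", "omega(NH2)", "omega(CH2)", "omega(CO2)",
    "rho(NH2)", "rho(CH2)", "rho(CO2)", "t(CH2)", "delta(NCC)",
}


def test_basis_has_21_named_modes_with_unit_coefficients():
    basis = build_local_mode_basis(glycinate_topology())
    assert len(basis) == 21                      # 3N-6 for N = 9
    assert {m.name for m in basis} == EXPECTED_NAMES
    for m in basis:
        assert m.coefficient_norm == pytest.approx(1.0, abs=1e-12)


def test_topology_validation():
    with pytest.raises(TopologyError):
        Topology(roles=["N"] * 9, indices=list(range(9)), bonds=[])
    good = glycinate_topology()
    with pytest.raises(TopologyError):
        Topology(roles=list(good.roles), indices=list(range(9)),
                 bonds=[(0, 1)])                 # disconnected graph


@pytest.mark.parametrize("kind,idx", [
    ("stretch", (0, 3)),
    ("bend", (1, 0, 2)),
    ("torsion", (1, 0, 3, 6)),
    ("oop", (3, 7, 8, 6)),
])
def test_s_vectors_match_numerical_gradient(kind, idx):
    _, x0 = glycinate_geometry()
    svecs, flags = primitive_s_vectors(kind, x0[None], idx)
    assert not flags.any()
    h = 1e-6
    for atom, s in svecs.items():
        for comp in range(3):
            xp = x0.copy()
            xm = x0.copy()
            xp[atom, comp] += h
            xm[atom, comp] -= h
            num = (primitive_value(kind, xp[None], idx)[0]
                   - primitive_value(kind, xm[None], idx)[0]) / (2 * h)
            assert s[0, comp] == pytest.approx(num, abs=5e-7)


def test_rigid_translation_gives_zero_mode_velocities():
    _, x0 = glycinate_geometry()
    n = 50
    v0 = np.array([0.01, -0.02, 0.005])
    pos = x0[None] + (np.arange(n) * 1.0)[:, None, None] * v0
    vel = np.tile(v0, (n, 9, 1))
    traj = Trajectory(species=["N", "H", "H", "C", "H", "H", "C", "O", "O"],
                      positions=pos, velocities=vel, timestep=1.0)
    topo = glycinate_topology()
    series = project_velocities(traj, build_local_mode_basis(topo), topo)
    assert np.abs(series.series).max() < 1e-10


def test_rigid_rotation_gives_zero_mode_velocities():
    species, x0 = glycinate_geometry()
    omega = np.array([2e-4, -1e-4, 3e-4])       # rad/fs, slow rotation
    n, dt = 40, 0.25
    com = x0.mean(axis=0)
    pos = np.empty((n, 9, 3))
    vel = np.empty((n, 9, 3))
    for f in range(n):
        th = np.linalg.norm(omega) * f * dt
        ax = omega / np.linalg.norm(omega)
        K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]],
                      [-ax[1], ax[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * K @ K
        pos[f] = (x0 - com) @ R.T + com
        vel[f] = np.cross(omega, pos[f] - com)
    traj = Trajectory(species=species, positions=pos, velocities=vel,
                      timestep=dt)
    topo = glycinate_topology()
    series = project_velocities(traj, build_local_mode_basis(topo), topo)
    # exact to first order: residual scales with |omega|·amplitude
    assert np.abs(series.series).max() < 1e-8


def test_pure_cn_oscillation_isolates_nu_cn():
    species, x0 = glycinate_geometry()
    n, dt = 2048, 0.25
    t = dt * np.arange(n)
    f0 = 950.0 * 2.99792458e-5                  # 950 cm⁻¹ in fs⁻¹
    u = (x0[3] - x0[0])
    u = u / np.linalg.norm(u)
    amp = 0.02
    pos = np.tile(x0, (n, 1, 1))
    vel = np.zeros((n, 9, 3))
    osc = amp * np.cos(2 * np.pi * f0 * t)
    dosc = -amp * 2 * np.pi * f0 * np.sin(2 * np.pi * f0 * t)
    # translate the whole amine group along the C–N axis: to first order this
    # changes only the CN bond length, leaving all other internals untouched
    for a in (0, 1, 2):
        pos[:, a] += osc[:, None] * u
        vel[:, a] = dosc[:, None] * u
    traj = Trajectory(species=species, positions=pos, velocities=vel,
                      timestep=dt)
    topo = glycinate_topology()
    basis = build_local_mode_basis(topo)
    series = project_velocities(traj, basis, topo)
    k_cn = series.names.index("nu(CN)")
    a_cn = np.abs(series.series[k_cn]).max()
    # the CN series is sinusoidal at f0 (r shrinks as the group moves toward CA)
    assert abs(np.corrcoef(series.series[k_cn], dosc)[0, 1]) > 0.9999
    assert a_cn == pytest.approx(np.abs(dosc).max(), rel=1e-3)
    # every other local mode stays below 1 % of the CN amplitude
    for k, name in enumerate(series.names):
        if name != "nu(CN)":
            assert np.abs(series.series[k]).max() < 0.01 * a_cn, name


def test_local_mode_spectra_unit_area_and_peaks(toy_single):
    traj = normal_mode_trajectory(toy_single.model, T=500.0, n_steps=8192,
                                  dt=0.25, seed=3)
    topo = toy_single.topologies[0]
    series = project_velocities(traj, build_local_mode_basis(topo), topo)
    specs = local_mode_spectra(series, window="hann")
    for name, sp in specs.items():
        assert sp.integral() == pytest.approx(1.0, abs=1e-8)
    # parameter recovery: each mode's dominant peak at its assigned frequency
    for name, nu in toy_single.mode_wavenumbers.items():
        sp = specs[name]
        assert abs(sp.peak_wavenumber() - nu) <= sp.resolution, name


def test_average_of_identical_molecules_is_identity(toy_single):
    traj = normal_mode_trajectory(toy_single.model, T=500.0, n_steps=2048,
                                  dt=0.25, seed=5)
    topo = toy_single.topologies[0]
    series = project_velocities(traj, build_local_mode_basis(topo), topo)
    one = local_mode_spectra(series)
    two = local_mode_spectra([series, series])
    for name in one:
        np.testing.assert_allclose(two[name].intensity, one[name].intensity,
                                   atol=1e-12)


def test_all_zero_series_rejected():
    species, x0 = glycinate_geometry()
    pos = np.tile(x0, (64, 1, 1))
    vel = np.zeros((64, 9, 3))
    traj = Trajectory(species=species, positions=pos, velocities=vel,
                      timestep=0.25)
    topo = glycinate_topology()
    series = project_velocities(traj, build_local_mode_basis(topo), topo)
    with pytest.raises(PreconditionError):
        local_mode_spectra(series)


def test_bond_stretch_series_matches_radial_velocity():
    n, dt = 512, 0.25
    t = dt * np.arange(n)
    r = 1.0 + 0.05 * np.sin(0.3 * t)
    rdot = 0.05 * 0.3 * np.cos(0.3 * t)
    pos = np.zeros((n, 2, 3))
    pos[:, 1, 0] = r
    vel = np.zeros((n, 2, 3))
    vel[:, 1, 0] = rdot
    traj = Trajectory(species=["Cu", "H"], positions=pos, velocities=vel,
                      timestep=dt)
    series = bond_stretch_series(traj, 0, 1)
    np.testing.assert_allclose(series.series[0], rdot, atol=1e-12)
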