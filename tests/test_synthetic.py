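"""Force models, integrators, the glycinate toy and the Morse oracle."""
import numpy as np
import pytest

from advib.constants import KB, wavenumber_to_angular
from advib.errors import IntegrationError, PreconditionError
from advib.spectra import mass_weighted_psd
from advib.structure import rms_symmetry_deviation, mean_structure, MeanStructure
from advib.synthetic import (DEFAULT_MODE_WAVENUMBERS, ForceModel,
                             IntegratorSpec, glycinate_toy, harmonic_atom,
                             integrate, maxwell_velocities,
                             morse_bond_reference, morse_toy,
                             normal_mode_trajectory)
from advib.trajectory import AtomSelection


def test_toy_normal_modes_match_requested_frequencies(toy_single):
    nus = toy_single.model.normal_mode_wavenumbers()
    internal = sorted(nus)[-21:]
    requested = sorted(DEFAULT_MODE_WAVENUMBERS.values())
    np.testing.assert_allclose(internal, requested, rtol=0.02)
    # mobile dof minus the 6 external attachment modes = 21 internal modes
    assert len(nus) == 27


def test_toy_custom_frequency_request():
    custom = dict(DEFAULT_MODE_WAVENUMBERS)
    custom["nu(CN)"] = 1000.0
    toy = glycinate_toy(wavenumbers=custom)
    nus = toy.model.normal_mode_wavenumbers()
    assert np.min(np.abs(nus - 1000.0)) < 1.0


def test_toy_rejects_bad_frequency_sets():
    with pytest.raises(PreconditionError):
        glycinate_toy(wavenumbers={"nu(CN)": -5.0})
    with pytest.raises(PreconditionError):
        glycinate_toy(wavenumbers={"not_a_mode": 100.0,
                                   **DEFAULT_MODE_WAVENUMBERS})


def test_glide_pair_equilibrium_is_exactly_symmetric(toy_pair):
    ms = MeanStructure(species=list(toy_pair.model.species),
                       positions=toy_pair.model.equilibrium.copy(),
                       n_frames_averaged=1, cell=toy_pair.model.cell)
    rms = rms_symmetry_deviation(ms, toy_pair.glide)
    assert rms["all"] == pytest.approx(0.0, abs=1e-10)


def test_nve_conserves_energy():
    model = harmonic_atom(1000.0, mass=1.00794, species="H")
    spec = IntegratorSpec(scheme="nve_velocity_verlet", T=300.0, dt=0.25,
                          n_steps=100_000, seed=2)
    traj = integrate(model, spec)
    m = model.masses[0]
    k = m * wavenumber_to_angular(1000.0) ** 2
    ke = 0.5 * m * np.sum(traj.velocities[:, 0] ** 2, axis=1)
    pe = 0.5 * k * np.sum(traj.positions[:, 0] ** 2, axis=1)
    E = ke + pe
    # velocity Verlet: the energy error oscillates but has no secular drift;
    # the fitted linear trend over 1e5 steps stays below 1e-5 relative
    slope = np.polyfit(np.arange(E.size), E, 1)[0]
    assert abs(slope) * E.size / E.mean() < 1e-5
    # and the oscillating error itself is bounded by O((ω dt)²)
    assert np.ptp(E) / E.mean() < 1e-3


def test_langevin_kinetic_temperature():
    model = harmonic_atom(600.0, mass=12.0)
    spec = IntegratorSpec(scheme="langevin", T=500.0, dt=0.25,
                          n_steps=2 ** 16, friction=2e-3, seed=4)
    traj = integrate(model, spec)
    v2 = np.sum(traj.velocities[2 ** 13:, 0] ** 2, axis=1)
    Tkin = (12.0 * v2 / (3 * KB)).mean()
    # batch-mean standard error over 16 batches
    batches = (12.0 * v2 / (3 * KB)).reshape(16, -1).mean(axis=1)
    se = batches.std(ddof=1) / np.sqrt(16)
    assert abs(Tkin - 500.0) < 3 * se + 1.0


def test_zero_temperature_langevin_is_static():
    model = harmonic_atom(600.0, mass=12.0)
    spec = IntegratorSpec(scheme="langevin", T=0.0, dt=0.25, n_steps=500,
                          friction=1e-3, seed=1, initial_velocities="zero")
    traj = integrate(model, spec)
    assert np.abs(traj.positions).max() < 1e-14
    assert np.abs(traj.velocities).max() < 1e-14


def test_nose_hoover_chain_thermalises():
    toy = glycinate_toy()
    spec = IntegratorSpec(scheme="nose_hoover_chain", T=500.0, dt=0.25,
                          n_steps=2 ** 15, tau=25.0, seed=6)
    traj = integrate(toy.model, spec)
    ke2 = np.einsum("fai,a->f", traj.velocities ** 2, traj.masses)
    Tkin = ke2[2 ** 13:].mean() / (27 * KB)
    assert Tkin == pytest.approx(500.0, rel=0.05)


def test_dt_stability_guard():
    model = harmonic_atom(3800.0, mass=1.00794, species="H")
    period = 2 * np.pi / wavenumber_to_angular(3800.0)   # ≈ 8.8 fs
    with pytest.raises(IntegrationError):
        integrate(model, IntegratorSpec(scheme="nve_velocity_verlet",
                                        dt=period / 2, n_steps=10))
    with pytest.warns(UserWarning):
        integrate(model, IntegratorSpec(scheme="nve_velocity_verlet",
                                        dt=period / 8, n_steps=10))


def test_mirrored_pair_dynamics_stay_mirror_images(toy_pair):
    """Glide-symmetric equations of motion with mirrored noise give exactly
    mirrored trajectories."""
    model = toy_pair.model
    R = toy_pair.glide.rotation
    t = toy_pair.glide.translation

    real_rng = np.random.default_rng

    class MirroredRng:
        """Feeds molecule 2 the mirror image of molecule 1's noise."""

        def __init__(self, seed):
            self.rng = real_rng(seed)

        def standard_normal(self, shape):
            out = np.empty(shape)
            half = self.rng.standard_normal((9, 3))
            out[:9] = half
            out[9:] = half @ R.T
            return out

    import advib.synthetic as syn
    spec = IntegratorSpec(scheme="langevin", T=500.0, dt=0.25, n_steps=400,
                          friction=1e-3, seed=3, initial_velocities="zero")
    try:
        np.random.default_rng = lambda seed=None: MirroredRng(seed)
        traj = syn.integrate(model, spec)
    finally:
        np.random.default_rng = real_rng
    img = traj.positions[:, :9] @ R.T + t
    np.testing.assert_allclose(img, traj.positions[:, 9:], atol=1e-10)


def test_maxwell_velocities_variance():
    rng = np.random.default_rng(0)
    masses = np.array([1.0, 12.0, 16.0] * 400)
    v = maxwell_velocities(masses, 500.0, rng)
    v2 = (masses[:, None] * v ** 2).mean()
    assert v2 == pytest.approx(KB * 500.0, rel=0.05)


def test_morse_reference_harmonic_limit():
    m = 1.00794
    nu0 = 1000.0
    # deep well: classical frequency at k_B·T tends to the harmonic value
    for ratio, tol in [(50.0, 0.011), (500.0, 0.0011)]:
        D = ratio * KB * 500.0
        a = wavenumber_to_angular(nu0) / np.sqrt(2 * D / m)
        nu = morse_bond_reference(D, a, m, 500.0)
        assert nu == pytest.approx(nu0, rel=tol)
        assert nu < nu0                       # always red of harmonic


def test_morse_reference_matches_closed_form():
    m, T = 1.00794, 500.0
    D = 10 * KB * T
    a = wavenumber_to_angular(1000.0) / np.sqrt(2 * D / m)
    nu = morse_bond_reference(D, a, m, T)
    exact = 1000.0 * np.sqrt(1.0 - KB * T / D)
    assert nu == pytest.approx(exact, rel=1e-8)


def test_morse_reference_rejects_unbound():
    with pytest.raises(PreconditionError):
        morse_bond_reference(KB * 100.0, 2.0, 1.0, 500.0)


def test_morse_redshift_monotone_in_temperature():
    m = 1.00794
    D = 10 * KB * 500.0
    a = wavenumber_to_angular(1000.0) / np.sqrt(2 * D / m)
    nus = [morse_bond_reference(D, a, m, T) for T in (100, 300, 500, 700)]
    assert all(b < a_ for a_, b in zip(nus, nus[1:]))


def test_position_variance_equipartition():
    """Thermostated harmonic mode: var(x) → k_B·T/(mω²) within 3 SE."""
    nu, m, T = 300.0, 12.0, 500.0
    model = harmonic_atom(nu, mass=m)
    spec = IntegratorSpec(scheme="langevin", T=T, dt=0.25, n_steps=2 ** 17,
                          friction=4e-3, seed=9)
    traj = integrate(model, spec)
    x = traj.positions[2 ** 14:, 0, :]
    pred = KB * T / (m * wavenumber_to_angular(nu) ** 2)
    var = x.var(axis=0).mean()
    batches = np.array([b.var(axis=0).mean()
                        for b in np.array_split(x, 16)])
    se = batches.std(ddof=1) / np.sqrt(16)
    assert abs(var - pred) < 3 * se
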