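"""Displacement matrices, thermal ellipsoids, shape classes, ADP export."""
import numpy as np
import pytest

from advib.ellipsoids import (DisplacementMatrix, displacement_matrices,
                              ellipsoid, read_adp_cif, shape_descriptor,
                              symmetrize_displacement_matrices, u_cart_to_cif,
                              write_adp_cif)
from advib.errors import PreconditionError
from advib.structure import GlideOperation, MeanStructure, mean_structure
from advib.trajectory import Trajectory


def test_static_atom_gives_zero_matrix():
    traj = Trajectory(species=["O"], positions=np.ones((20, 1, 3)), timestep=1.0)
    ms = mean_structure(traj)
    (dm,) = displacement_matrices(traj, ms)
    np.testing.assert_allclose(dm.U, 0.0, atol=1e-14)


def test_cosine_displacement_second_moment():
    n = 4000
    t = np.arange(n)
    A, nu = 0.3, 10.0 / n          # whole periods in the window
    pos = np.zeros((n, 1, 3))
    pos[:, 0, 0] = A * np.cos(2 * np.pi * nu * t)
    traj = Trajectory(species=["O"], positions=pos, timestep=1.0)
    ms = mean_structure(traj)
    (dm,) = displacement_matrices(traj, ms)
    assert dm.U[0, 0] == pytest.approx(A ** 2 / 2, rel=1e-6)
    assert abs(dm.U[1, 1]) < 1e-14 and abs(dm.U[0, 1]) < 1e-14


def test_isotropic_gaussian_monte_carlo():
    rng = np.random.default_rng(42)
    n, sigma = 100_000, 0.1
    pos = rng.normal(scale=sigma, size=(n, 1, 3))
    traj = Trajectory(species=["O"], positions=pos, timestep=1.0)
    ms = mean_structure(traj)
    (dm,) = displacement_matrices(traj, ms)
    se = sigma ** 2 * np.sqrt(2.0 / n)       # SE of a variance estimate
    assert np.all(np.abs(np.diag(dm.U) - sigma ** 2) < 3 * se)


def test_trace_equals_mean_squared_displacement():
    rng = np.random.default_rng(1)
    pos = rng.normal(size=(5000, 2, 3)) * 0.2
    traj = Trajectory(species=["O", "O"], positions=pos, timestep=1.0)
    ms = mean_structure(traj)
    dms = displacement_matrices(traj, ms)
    u = pos - pos.mean(axis=0)
    for a, dm in enumerate(dms):
        msd = np.mean(np.sum(u[:, a] ** 2, axis=1))
        assert np.trace(dm.U) == pytest.approx(msd, abs=1e-10)


def test_ellipsoid_closed_form_and_scale():
    dm = DisplacementMatrix(U=np.diag([4e-2, 1e-2, 1e-2]), atom_index=0)
    e = ellipsoid(dm, scale=1.5382)
    np.testing.assert_allclose(e.semiaxes, [0.30764, 0.15382, 0.15382],
                               atol=1e-10)
    np.testing.assert_allclose(e.eigenvalues, [4e-2, 1e-2, 1e-2], atol=1e-14)
    np.testing.assert_allclose(e.axes @ e.axes.T, np.eye(3), atol=1e-10)


def test_ellipsoid_isotropic_sphere():
    e = ellipsoid(DisplacementMatrix(U=0.04 * np.eye(3), atom_index=0), scale=2.0)
    np.testing.assert_allclose(e.semiaxes, 0.4, atol=1e-12)


def test_ellipsoid_rotation_equivariance():
    rng = np.random.default_rng(3)
    A = rng.normal(size=(3, 3))
    U = A @ A.T * 1e-2
    th = 0.8
    R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0],
                  [0, 0, 1.0]])
    e1 = ellipsoid(DisplacementMatrix(U=U, atom_index=0))
    e2 = ellipsoid(DisplacementMatrix(U=R @ U @ R.T, atom_index=0))
    np.testing.assert_allclose(e2.eigenvalues, e1.eigenvalues, atol=1e-12)
    for ax1, ax2 in zip(e1.axes, e2.axes):
        rotated = R @ ax1
        assert min(np.linalg.norm(ax2 - rotated),
                   np.linalg.norm(ax2 + rotated)) < 1e-8


def test_negative_eigenvalue_rejected():
    U = np.diag([1e-2, 1e-2, -1e-5])
    with pytest.raises(PreconditionError):
        ellipsoid(U)


@pytest.mark.parametrize("semiaxes,expected", [
    ((2.0, 1.0, 1.0), "prolate"),
    ((2.0, 2.0, 1.0), "oblate"),
    ((1.04, 1.02, 1.00), "spherical"),
    ((2.0, 1.5, 1.0), "triaxial"),
])
def test_shape_classification(semiaxes, expected):
    e = ellipsoid(DisplacementMatrix(U=np.diag(np.array(semiaxes)[::-1] ** 2),
                                     atom_index=0), scale=1.0)
    assert shape_descriptor(e, tol=0.05).shape_class == expected
    assert shape_descriptor(e).anisotropy_ratio >= 1.0


def test_symmetrized_matrices_are_mirror_images():
    R = np.diag([1.0, -1.0, 1.0])
    rng = np.random.default_rng(7)
    A = rng.normal(size=(3, 3))
    B = rng.normal(size=(3, 3))
    U0 = DisplacementMatrix(U=A @ A.T * 1e-2, atom_index=0)
    U1 = DisplacementMatrix(U=B @ B.T * 1e-2, atom_index=1)
    glide = GlideOperation(rotation=R, translation=np.zeros(3),
                           permutation=np.array([1, 0]))
    sym = symmetrize_displacement_matrices([U0, U1], glide)
    # exact invariance: R Ũ_i Rᵀ = Ũ_σ(i)
    np.testing.assert_allclose(R @ sym[0].U @ R.T, sym[1].U, atol=1e-12)
    # idempotent
    again = symmetrize_displacement_matrices(sym, glide)
    for s, a in zip(sym, again):
        np.testing.assert_allclose(s.U, a.U, atol=1e-14)
    # partner ellipsoids: equal semiaxes, axes related by R
    e0, e1 = (ellipsoid(s) for s in sym)
    np.testing.assert_allclose(e0.semiaxes, e1.semiaxes, atol=1e-12)
    for ax0, ax1 in zip(e0.axes, e1.axes):
        m = R @ ax0
        assert min(np.linalg.norm(ax1 - m), np.linalg.norm(ax1 + m)) < 1e-8


def test_hand_computed_symmetrization():
    # U_a = diag(1,0,0)·s and a partner whose mirror image is diag(0,1,0)·s
    s = 0.02
    R = np.array([[0.0, 1.0, 0], [1.0, 0.0, 0], [0, 0, 1.0]])   # mirror x<->y
    Ua = DisplacementMatrix(U=np.diag([s, 0, 0]), atom_index=0)
    Ub = DisplacementMatrix(U=np.diag([s, 0, 0]), atom_index=1)
    glide = GlideOperation(rotation=R, translation=np.zeros(3),
                           permutation=np.array([1, 0]))
    sym = symmetrize_displacement_matrices([Ua, Ub], glide)
    np.testing.assert_allclose(sym[0].U, np.diag([s / 2, s / 2, 0]), atol=1e-14)
    np.testing.assert_allclose(sym[1].U, np.diag([s / 2, s / 2, 0]), atol=1e-14)


def test_adp_cif_roundtrip(tmp_path):
    rng = np.random.default_rng(9)
    cell = np.array([[10.0, 0, 0], [1.5, 9.0, 0], [0.5, -0.3, 20.0]])
    ms = MeanStructure(species=["N", "O"],
                       positions=rng.uniform(1, 5, size=(2, 3)),
                       n_frames_averaged=1, cell=cell)
    U_set = []
    for i in range(2):
        A = rng.normal(size=(3, 3)) * 0.1
        U_set.append(DisplacementMatrix(U=A @ A.T, atom_index=i))
    path = tmp_path / "adp.cif"
    write_adp_cif(ms, U_set, path)
    species, frac, U_back, cell_back = read_adp_cif(path)
    assert species == ["N", "O"]
    for dm, Ub in zip(U_set, U_back):
        np.testing.assert_allclose(Ub, dm.U, atol=1e-8)


def test_adp_cif_isotropic_cubic(tmp_path):
    cell = np.diag([10.0, 10.0, 10.0])
    Ucif = u_cart_to_cif(0.01 * np.eye(3), cell)
    np.testing.assert_allclose(Ucif, 0.01 * np.eye(3), atol=1e-14)

    ms = MeanStructure(species=["C"], positions=np.array([[1.0, 2.0, 3.0]]),
                       n_frames_averaged=1, cell=cell)
    path = tmp_path / "iso.cif"
    write_adp_cif(ms, [DisplacementMatrix(U=0.01 * np.eye(3), atom_index=0)],
                  path)
    import gemmi
    blk = gemmi.cif.read(str(path)).sole_block()   # parses as valid CIF
    assert float(list(blk.find_loop("_atom_site_aniso_U_11"))[0]) == \
        pytest.approx(0.01, abs=1e-12)
    assert list(blk.find_loop("_atom_site_fract_x"))[0].startswith("0.1")
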