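"""Atomic displacement matrices and thermal ellipsoids.

With u the instantaneous Cartesian displacement of an atom from its mean
position, the displacement matrix U = ⟨u uᵀ⟩ (Å²) is symmetric positive
semidefinite; its eigenvectors give the principal axes of the atom's thermal
ellipsoid and the semiaxis lengths are scale·√λ.  The default probability
scale factor 1.5382 draws the 50 % surface of the trivariate Gaussian; values
slightly above enclose slightly more than half the probability.

Cartesian U can be exported as crystallographic anisotropic displacement
parameters (CIF ``_atom_site_aniso_U_ij``, referred to the reciprocal-axis
basis in the standard convention).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import PreconditionError
from .structure import GlideOperation, MeanStructure
from .trajectory import AtomSelection, Trajectory, full_selection

__all__ = [
    "DisplacementMatrix",
    "ThermalEllipsoid",
    "ShapeDescriptor",
    "KRONENBURG_SCALE",
    "displacement_matrices",
    "symmetrize_displacement_matrices",
    "ellipsoid",
    "shape_descriptor",
    "write_adp_cif",
    "read_adp_cif",
]

#: 50 % probability surface of a trivariate Gaussian (configurable default).
KRONENBURG_SCALE = 1.5382


@dataclass
class DisplacementMatrix:
    """Symmetric PSD 3×3 second-moment matrix of an atom's displacement."""

    U: np.ndarray              # (3, 3) Å²
    atom_index: int

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        if self.U.shape != (3, 3):
            raise PreconditionError("U must be 3x3")
        if not np.allclose(self.U, self.U.T, atol=1e-12):
            raise PreconditionError("U must be symmetric")
        if np.linalg.eigvalsh(self.U).min() < -1e-12:
            raise PreconditionError("U must be positive semidefinite")


@dataclass
class ThermalEllipsoid:
    """Eigen-decomposed displacement matrix with probability scaling."""

    semiaxes: np.ndarray       # (3,) Å, descending
    axes: np.ndarray           # (3, 3), rows are orthonormal directions
    scale: float
    eigenvalues: np.ndarray    # (3,) Å², descending


@dataclass
class ShapeDescriptor:
    """Qualitative ellipsoid shape (prolate cigar / oblate disc / ...)."""

    anisotropy_ratio: float
    shape_class: str           # prolate | oblate | triaxial | spherical
    tol: float


def displacement_matrices(traj: Trajectory,
                          mean: MeanStructure,
                          selection: AtomSelection | None = None,
                          ) -> list[DisplacementMatrix]:
    """Time-averaged outer product of displacements from the mean position.

    The trajectory must be unwrapped and the mean computed from the same
    frames; atoms are taken from ``selection`` (default: all), which must
    match the ordering of ``mean``.
    """
    sel = selection if selection is not None else full_selection(traj)
    sel.validate(traj.n_atoms)
    idx = sel.asarray()
    if len(idx) != mean.n_atoms:
        raise PreconditionError("mean structure does not match the selection")
    for k, i in enumerate(idx):
        if traj.species[i] != mean.species[k]:
            raise PreconditionError(
                f"species mismatch at selection position {k}: "
                f"{traj.species[i]} vs {mean.species[k]}")
    u = traj.positions[:, idx] - mean.positions[None, :, :]
    U = np.einsum("fai,faj->aij", u, u) / traj.n_frames
    U = 0.5 * (U + np.transpose(U, (0, 2, 1)))   # enforce exact symmetry
    return [DisplacementMatrix(U=U[k], atom_index=int(i))
            for k, i in enumerate(idx)]


def symmetrize_displacement_matrices(U_set: list[DisplacementMatrix],
                                     glide: GlideOperation,
                                     ) -> list[DisplacementMatrix]:
    """Impose perfect glide symmetry: Ũ_i = ½(U_i + R U_σ(i) Rᵀ).

    The output set is exactly invariant under the operation; applying the
    symmetrization twice is the same as applying it once.
    """
    n = len(U_set)
    if len(glide.permutation) != n:
        raise PreconditionError("glide permutation size mismatch")
    R = glide.rotation
    out = []
    for i, dm in enumerate(U_set):
        Up = U_set[glide.permutation[i]].U
        Ut = 0.5 * (dm.U + R.T @ Up @ R)
        out.append(DisplacementMatrix(U=0.5 * (Ut + Ut.T),
                                      atom_index=dm.atom_index))
    return out


def ellipsoid(U: DisplacementMatrix | np.ndarray,
              scale: float = KRONENBURG_SCALE) -> ThermalEllipsoid:
    """Eigen-decompose a displacement matrix into a thermal ellipsoid.

    Semiaxes are ``scale·√λ`` ordered descending; each axis sign is fixed by
    making its largest-magnitude component positive so output is
    deterministic.  Degenerate eigenvalues yield an arbitrary orthonormal
    completion.
    """
    M = U.U if isinstance(U, DisplacementMatrix) else np.asarray(U, dtype=float)
    lam, vec = np.linalg.eigh(M)
    if lam.min() < -1e-9:
        raise PreconditionError(
            f"displacement matrix has negative eigenvalue {lam.min():.3e} Å²")
    lam = np.clip(lam, 0.0, None)[::-1]
    vec = vec[:, ::-1].T            # rows are eigenvectors, descending λ
    for k in range(3):
        j = int(np.argmax(np.abs(vec[k])))
        if vec[k, j] < 0:
            vec[k] = -vec[k]
    return ThermalEllipsoid(semiaxes=scale * np.sqrt(lam), axes=vec,
                            scale=float(scale), eigenvalues=lam)


def shape_descriptor(e: ThermalEllipsoid, tol: float = 0.05) -> ShapeDescriptor:
    """Classify an ellipsoid as prolate, oblate, spherical or triaxial.

    Two semiaxes "agree" when their ratio is within ``tol`` of 1.
    """
    a, b, c = e.semiaxes          # descending
    if not c > 0:
        raise PreconditionError("semiaxes must be positive")
    ratio = a / c

    def close(p, q):
        return p / q - 1.0 <= tol      # p ≥ q by ordering

    if close(a, c):
        cls = "spherical"
    elif close(b, c) and not close(a, b):
        cls = "prolate"
    elif close(a, b) and not close(b, c):
        cls = "oblate"
    else:
        cls = "triaxial"
    return ShapeDescriptor(anisotropy_ratio=float(ratio), shape_class=cls,
                           tol=float(tol))


# ---------------------------------------------------------------------------
# crystallographic ADP export
# ---------------------------------------------------------------------------

def _cell_matrices(cell: np.ndarray):
    """Fractionalisation helpers: M (cart = M·frac) and N = diag(a_i*)."""
    M = np.asarray(cell, dtype=float).T     # columns are lattice vectors
    if abs(np.linalg.det(M)) < 1e-12:
        raise PreconditionError("singular cell")
    G = np.linalg.inv(M)                    # rows are reciprocal vectors
    N = np.diag(np.linalg.norm(G, axis=1))
    return M, G, N


def u_cart_to_cif(U_cart: np.ndarray, cell: np.ndarray) -> np.ndarray:
    """Cartesian U → CIF U (reciprocal-axis basis): U_cif = N⁻¹ G U Gᵀ N⁻¹."""
    _, G, N = _cell_matrices(cell)
    Ninv = np.linalg.inv(N)
    return Ninv @ G @ U_cart @ G.T @ Ninv


def u_cif_to_cart(U_cif: np.ndarray, cell: np.ndarray) -> np.ndarray:
    """Inverse of :func:`u_cart_to_cif`: U_cart = M N U_cif Nᵀ Mᵀ."""
    M, _, N = _cell_matrices(cell)
    return M @ N @ U_cif @ N.T @ M.T


def _cell_parameters(cell: np.ndarray):
    a, b, c = (np.linalg.norm(v) for v in cell)
    def ang(u, v):
        return float(np.degrees(np.arccos(np.dot(u, v) /
                                          (np.linalg.norm(u) * np.linalg.norm(v)))))
    return a, b, c, ang(cell[1], cell[2]), ang(cell[0], cell[2]), ang(cell[0], cell[1])


def write_adp_cif(structure: MeanStructure,
                  U_set: list[DisplacementMatrix],
                  path) -> None:
    """Write mean positions and anisotropic U_ij to a CIF file.

    Fractional coordinates and the six U_ij components follow the standard
    crystallographic convention (U referred to the reciprocal-axis basis).
    Round-trips exactly for cells in the standard (lower-triangular)
    orientation; for arbitrarily rotated cells the recovered Cartesian U is
    expressed in the standard frame.
    """
    if structure.cell is None:
        raise PreconditionError("ADP export requires a cell")
    if len(U_set) != structure.n_atoms:
        raise PreconditionError("U set size does not match structure")
    cell = structure.cell
    a, b, c, al, be, ga = _cell_parameters(cell)
    Minv = np.linalg.inv(cell.T)

    doc = gemmi.cif.Document()
    blk = doc.add_new_block("advib_adp")
    for key, val in (("_cell_length_a", a), ("_cell_length_b", b),
                     ("_cell_length_c", c), ("_cell_angle_alpha", al),
                     ("_cell_angle_beta", be), ("_cell_angle_gamma", ga)):
        blk.set_pair(key, f"{val:.8f}")
    blk.set_pair("_symmetry_space_group_name_H-M", gemmi.cif.quote("P 1"))

    labels = [f"{s}{i+1}" for i, s in enumerate(structure.species)]
    loop = blk.init_loop("_atom_site_", ["label", "type_symbol",
                                         "fract_x", "fract_y", "fract_z"])
    for lab, sym, pos in zip(labels, structure.species, structure.positions):
        f = Minv @ pos
        loop.add_row([lab, sym] + [f"{x:.10f}" for x in f])

    loop = blk.init_loop("_atom_site_aniso_", ["label", "U_11", "U_22", "U_33",
                                               "U_12", "U_13", "U_23"])
    for lab, dm in zip(labels, U_set):
        Uc = u_cart_to_cif(dm.U, cell)
        loop.add_row([lab] + [f"{v:.10e}" for v in
                              (Uc[0, 0], Uc[1, 1], Uc[2, 2],
                               Uc[0, 1], Uc[0, 2], Uc[1, 2])])
    doc.write_file(str(path))


def read_adp_cif(path):
    """Read back a CIF written by :func:`write_adp_cif`.

    Returns ``(species, frac_coords, U_cart_list, cell)`` with the cell
    reconstructed in the standard orientation (a along x, b in the xy plane).
    """
    blk = gemmi.cif.read(str(path)).sole_block()
    def fval(key):
        return float(blk.find_value(key))
    uc = gemmi.UnitCell(fval("_cell_length_a"), fval("_cell_length_b"),
                        fval("_cell_length_c"), fval("_cell_angle_alpha"),
                        fval("_cell_angle_beta"), fval("_cell_angle_gamma"))
    M = np.array(uc.orth.mat.tolist())      # cart = M · frac
    cell = M.T                              # rows are lattice vectors
    species = [s for s in blk.find_loop("_atom_site_type_symbol")]
    frac = np.array([[float(v) for v in blk.find_loop(f"_atom_site_fract_{ax}")]
                     for ax in "xyz"]).T
    comp = {k: [float(v) for v in blk.find_loop(f"_atom_site_aniso_U_{k}")]
            for k in ("11", "22", "33", "12", "13", "23")}
    U_cart = []
    for i in range(len(species)):
        Ucif = np.array([[comp["11"][i], comp["12"][i], comp["13"][i]],
                         [comp["12"][i], comp["22"][i], comp["23"][i]],
                         [comp["13"][i], comp["23"][i], comp["33"][i]]])
        U_cart.append(u_cif_to_cart(Ucif, cell))
    return species, frac, U_cart, cell
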