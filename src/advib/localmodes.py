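"""Generalized local-mode (internal) coordinates for a glycinate adsorbate.

The glycinate anion NH2–CH2–CO2 (9 atoms) supports 3N−6 = 21 internal
coordinates, built here from the classical group-vibration combinations:
symmetric/antisymmetric XH2 (and CO2) stretches (Δr1 ± Δr2)/√2, skeletal CN
and CC stretches, scissor/wag/rock/twist bend combinations, torsions about
the CN and CC bonds, and the NCC skeletal scissor.  Each coordinate carries
a normalised coefficient vector over primitive internals (stretch, bend,
torsion, out-of-plane), and the Wilson s-vectors of the primitives are
recomputed from the instantaneous geometry every frame, so the projection

    q̇_k(t) = Σ_p c_p Σ_a s_p,a(x(t)) · v_a(t)

remains valid for the large-amplitude motion seen at 500 K.  Internal
coordinates annihilate rigid translations exactly and rigid rotations to
first order.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .constants import C_CM_PER_FS
from .errors import PreconditionError, TopologyError
from .spectra import Spectrum, mass_weighted_psd, normalize_unit_area
from .trajectory import AtomSelection, Trajectory

__all__ = [
    "Topology",
    "LocalModeDefinition",
    "ModeVelocitySeries",
    "GLYCINATE_ROLES",
    "glycinate_topology",
    "build_local_mode_basis",
    "project_velocities",
    "local_mode_spectra",
]

#: Canonical role order used by the bundled glycinate topology.
GLYCINATE_ROLES = ("N", "H_N", "H_N", "C_alpha", "H_C", "H_C",
                   "C_carboxyl", "O", "O")

_ROLE_MULTIPLICITY = {"N": 1, "H_N": 2, "C_alpha": 1, "H_C": 2,
                      "C_carboxyl": 1, "O": 2}

_ROLE_ELEMENT = {"N": "N", "H_N": "H", "C_alpha": "C", "H_C": "H",
                 "C_carboxyl": "C", "O": "O"}


@dataclass
class Topology:
    """Atom roles and bonds of one glycinate-family molecule.

    ``atoms`` maps trajectory atom indices to roles; ``bonds`` are index
    pairs.  Roles must match the glycinate multiplicities and the bond graph
    must be connected.
    """

    roles: list[str]               # role per atom, molecule-local order
    indices: list[int]             # trajectory atom index per molecule atom
    bonds: list[tuple[int, int]]   # pairs of *molecule-local* positions

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for r in self.roles:
            counts[r] = counts.get(r, 0) + 1
        if counts != _ROLE_MULTIPLICITY:
            raise TopologyError(
                f"role multiplicities {counts} do not match glycinate "
                f"{_ROLE_MULTIPLICITY}")
        if len(self.indices) != len(self.roles):
            raise TopologyError("indices/roles length mismatch")
        n = len(self.roles)
        adj = {i: set() for i in range(n)}
        for a, b in self.bonds:
            if not (0 <= a < n and 0 <= b < n):
                raise TopologyError(f"bond ({a},{b}) out of range")
            adj[a].add(b)
            adj[b].add(a)
        seen = {0}
        stack = [0]
        while stack:
            for j in adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(seen) != n:
            raise TopologyError("bond graph is not connected")

    def role_positions(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == role]

    @classmethod
    def from_yaml(cls, path) -> "Topology":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(roles=list(d["roles"]),
                   indices=list(d.get("indices", range(len(d["roles"])))),
                   bonds=[tuple(b) for b in d["bonds"]])

    def element(self, pos: int) -> str:
        return _ROLE_ELEMENT[self.roles[pos]]


def glycinate_topology(first_atom: int = 0) -> Topology:
    """Bundled 9-atom glycinate topology starting at a trajectory index.

    Molecule-local order: N, H_N×2, C_alpha, H_C×2, C_carboxyl, O×2.
    """
    bonds = [(0, 1), (0, 2), (0, 3), (3, 4), (3, 5), (3, 6), (6, 7), (6, 8)]
    return Topology(roles=list(GLYCINATE_ROLES),
                    indices=list(range(first_atom, first_atom + 9)),
                    bonds=bonds)


@dataclass
class LocalModeDefinition:
    """A named internal coordinate as a combination of primitives.

    Each primitive is ``(kind, molecule-local atom positions, coefficient)``
    with kind ∈ {stretch, bend, torsion, oop}; the coefficient vector is
    normalised to unit Euclidean norm on construction.
    """

    name: str
    primitives: list[tuple[str, tuple[int, ...], float]]

    def __post_init__(self) -> None:
        norm = float(np.sqrt(sum(c * c for _, _, c in self.primitives)))
        if norm == 0:
            raise PreconditionError(f"mode {self.name} has zero coefficients")
        self.primitives = [(k, tuple(idx), c / norm)
                           for k, idx, c in self.primitives]

    @property
    def coefficient_norm(self) -> float:
        return float(np.sqrt(sum(c * c for _, _, c in self.primitives)))


@dataclass
class ModeVelocitySeries:
    """Per-mode internal-coordinate velocity time series q̇_k(t)."""

    names: list[str]
    series: np.ndarray             # (n_modes, n_frames)
    timestep: float                # fs
    flagged_fraction: float = 0.0  # fraction of frames with degenerate geometry


def build_local_mode_basis(topology: Topology) -> list[LocalModeDefinition]:
    """The 21 glycinate local modes (6 stretch + 2 skeletal + 2 torsion +
    9 scissor/wag/rock + CH2 twist + NCC scissor).

    XH2 stretches combine the two X–H bond stretches as (Δr1 ± Δr2)/√2.
    For the terminal NH2 and CO2 groups wag/rock use the symmetric and
    antisymmetric combinations of the two H(O)–X–skeleton bends, except the
    planar CO2 wag which is the Wilson out-of-plane coordinate of the
    skeletal carbon bond against the OCO plane.  The methylene group, with
    two skeletal neighbours, uses the four flanking bends in the standard
    ± pattern (wag: ++−−, rock: +−+−, twist: +−−+).
    """
    N = topology.role_positions("N")[0]
    HN1, HN2 = topology.role_positions("H_N")
    CA = topology.role_positions("C_alpha")[0]
    HA1, HA2 = topology.role_positions("H_C")
    C = topology.role_positions("C_carboxyl")[0]
    O1, O2 = topology.role_positions("O")
    s = 1.0 / np.sqrt(2.0)
    defs = [
        LocalModeDefinition("nu_s(NH2)", [("stretch", (N, HN1), s),
                                          ("stretch", (N, HN2), s)]),
        LocalModeDefinition("nu_a(NH2)", [("stretch", (N, HN1), s),
                                          ("stretch", (N, HN2), -s)]),
        LocalModeDefinition("nu_s(CH2)", [("stretch", (CA, HA1), s),
                                          ("stretch", (CA, HA2), s)]),
        LocalModeDefinition("nu_a(CH2)", [("stretch", (CA, HA1), s),
                                          ("stretch", (CA, HA2), -s)]),
        LocalModeDefinition("nu_s(CO2)", [("stretch", (C, O1), s),
                                          ("stretch", (C, O2), s)]),
        LocalModeDefinition("nu_a(CO2)", [("stretch", (C, O1), s),
                                          ("stretch", (C, O2), -s)]),
        LocalModeDefinition("nu(CN)", [("stretch", (N, CA), 1.0)]),
        LocalModeDefinition("nu(CC)", [("stretch", (CA, C), 1.0)]),
        LocalModeDefinition("tau(CN)", [("torsion", (HN1, N, CA, C), s),
                                        ("torsion", (HN2, N, CA, C), s)]),
        LocalModeDefinition("tau(CC)", [("torsion", (O1, C, CA, N), s),
                                        ("torsion", (O2, C, CA, N), s)]),
        LocalModeDefinition("delta(NH2)", [("bend", (HN1, N, HN2), 1.0)]),
        LocalModeDefinition("delta(CH2)", [("bend", (HA1, CA, HA2), 1.0)]),
        LocalModeDefinition("delta(CO2)", [("bend", (O1, C, O2), 1.0)]),
        LocalModeDefinition("omega(NH2)", [("bend", (HN1, N, CA), s),
                                           ("bend", (HN2, N, CA), s)]),
        LocalModeDefinition("rho(NH2)", [("bend", (HN1, N, CA), s),
                                         ("bend", (HN2, N, CA), -s)]),
        LocalModeDefinition("omega(CH2)", [("bend", (HA1, CA, N), 0.5),
                                           ("bend", (HA2, CA, N), 0.5),
                                           ("bend", (HA1, CA, C), -0.5),
                                           ("bend", (HA2, CA, C), -0.5)]),
        LocalModeDefinition("rho(CH2)", [("bend", (HA1, CA, N), 0.5),
                                         ("bend", (HA2, CA, N), -0.5),
                                         ("bend", (HA1, CA, C), 0.5),
                                         ("bend", (HA2, CA, C), -0.5)]),
        LocalModeDefinition("t(CH2)", [("bend", (HA1, CA, N), 0.5),
                                       ("bend", (HA2, CA, N), -0.5),
                                       ("bend", (HA1, CA, C), -0.5),
                                       ("bend", (HA2, CA, C), 0.5)]),
        LocalModeDefinition("omega(CO2)", [("oop", (CA, O1, O2, C), 1.0)]),
        LocalModeDefinition("rho(CO2)", [("bend", (O1, C, CA), s),
                                         ("bend", (O2, C, CA), -s)]),
        LocalModeDefinition("delta(NCC)", [("bend", (N, CA, C), 1.0)]),
    ]
    assert len(defs) == 21
    return defs


# ---------------------------------------------------------------------------
# Wilson s-vectors, vectorised over frames
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray):
    r = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / r, r[..., 0]


def _stretch_s(p: np.ndarray, idx):
    """p: (F, N, 3).  Returns ({atom: (F,3)}, flags (F,))."""
    a, b = idx
    u, _ = _unit(p[:, a] - p[:, b])
    return {a: u, b: -u}, np.zeros(p.shape[0], dtype=bool)


def _bend_s(p: np.ndarray, idx):
    """Bend a–c–b with central atom second in ``idx`` = (a, c, b)."""
    a, c, b = idx
    u, ru = _unit(p[:, a] - p[:, c])
    v, rv = _unit(p[:, b] - p[:, c])
    cos = np.sum(u * v, axis=-1)
    cos = np.clip(cos, -1.0, 1.0)
    sin = np.sqrt(1.0 - cos ** 2)
    flags = sin < 1e-3
    sin_safe = np.where(flags, 1.0, sin)
    sa = (cos[:, None] * u - v) / (ru * sin_safe)[:, None]
    sb = (cos[:, None] * v - u) / (rv * sin_safe)[:, None]
    return {a: sa, b: sb, c: -(sa + sb)}, flags


def _torsion_s(p: np.ndarray, idx):
    """Dihedral a–b–c–d (Blondel–Karplus gradient)."""
    a, b, c, d = idx
    F = p[:, a] - p[:, b]
    G = p[:, b] - p[:, c]
    H = p[:, d] - p[:, c]
    A = np.cross(F, G)
    B = np.cross(H, G)
    g = np.linalg.norm(G, axis=-1)
    A2 = np.sum(A * A, axis=-1)
    B2 = np.sum(B * B, axis=-1)
    flags = (A2 < 1e-12) | (B2 < 1e-12)
    A2s = np.where(flags, 1.0, A2)
    B2s = np.where(flags, 1.0, B2)
    sa = (g / A2s)[:, None] * A
    sd = -(g / B2s)[:, None] * B
    fg = np.sum(F * G, axis=-1) / g ** 2
    hg = np.sum(H * G, axis=-1) / g ** 2
    sb = -(1.0 + fg)[:, None] * sa - hg[:, None] * sd
    sc = -(sa + sb + sd)
    return {a: sa, b: sb, c: sc, d: sd}, flags


def _oop_s(p: np.ndarray, idx):
    """Wilson out-of-plane bend: apex atom 1 against plane (2, 3) at centre 4.

    ``idx`` = (apex, plane_a, plane_b, central); the coordinate is the angle
    γ between the central→apex bond and the plane through centre and the two
    plane atoms.
    """
    i1, i2, i3, i4 = idx
    e1, r1 = _unit(p[:, i1] - p[:, i4])
    e2, r2 = _unit(p[:, i2] - p[:, i4])
    e3, r3 = _unit(p[:, i3] - p[:, i4])
    cosphi = np.clip(np.sum(e2 * e3, axis=-1), -1.0, 1.0)
    sinphi = np.sqrt(1.0 - cosphi ** 2)
    cross23 = np.cross(e2, e3)
    singam = np.clip(np.sum(cross23 * e1, axis=-1) / np.where(sinphi < 1e-8, 1.0, sinphi),
                     -1.0, 1.0)
    cosgam = np.sqrt(np.clip(1.0 - singam ** 2, 0.0, None))
    flags = (sinphi < 1e-3) | (cosgam < 1e-3)
    sp = np.where(flags, 1.0, sinphi)
    cg = np.where(flags, 1.0, cosgam)
    tg = singam / cg
    s1 = ((np.cross(e2, e3) / (cg * sp)[:, None]) - (tg[:, None] * e1)) / r1[:, None]
    s2 = ((np.cross(e3, e1) / (cg * sp)[:, None])
          - (tg / sp ** 2)[:, None] * (e2 - cosphi[:, None] * e3)) / r2[:, None]
    s3 = ((np.cross(e1, e2) / (cg * sp)[:, None])
          - (tg / sp ** 2)[:, None] * (e3 - cosphi[:, None] * e2)) / r3[:, None]
    s4 = -(s1 + s2 + s3)
    return {i1: s1, i2: s2, i3: s3, i4: s4}, flags


_PRIMITIVE_S = {"stretch": _stretch_s, "bend": _bend_s,
                "torsion": _torsion_s, "oop": _oop_s}


def primitive_value(kind: str, p: np.ndarray, idx) -> np.ndarray:
    """Value of a primitive internal coordinate per frame (Å or rad)."""
    if kind == "stretch":
        a, b = idx
        return np.linalg.norm(p[:, a] - p[:, b], axis=-1)
    if kind == "bend":
        a, c, b = idx
        u, _ = _unit(p[:, a] - p[:, c])
        v, _ = _unit(p[:, b] - p[:, c])
        return np.arccos(np.clip(np.sum(u * v, axis=-1), -1.0, 1.0))
    if kind == "torsion":
        a, b, c, d = idx
        F = p[:, a] - p[:, b]
        G = p[:, b] - p[:, c]
        H = p[:, d] - p[:, c]
        A = np.cross(F, G)
        B = np.cross(H, G)
        gn = np.linalg.norm(G, axis=-1)
        return np.arctan2(np.sum(np.cross(A, B) * G, axis=-1) / gn,
                          np.sum(A * B, axis=-1))
    if kind == "oop":
        i1, i2, i3, i4 = idx
        e1, _ = _unit(p[:, i1] - p[:, i4])
        e2, _ = _unit(p[:, i2] - p[:, i4])
        e3, _ = _unit(p[:, i3] - p[:, i4])
        sinphi = np.linalg.norm(np.cross(e2, e3), axis=-1)
        return np.arcsin(np.clip(np.sum(np.cross(e2, e3) * e1, axis=-1)
                                 / np.where(sinphi < 1e-8, 1.0, sinphi), -1, 1))
    raise PreconditionError(f"unknown primitive kind {kind!r}")


def primitive_s_vectors(kind: str, p: np.ndarray, idx):
    """Wilson s-vectors of a primitive at each frame.

    Returns ``(svecs, flags)`` with ``svecs`` a dict atom → (F, 3) array and
    ``flags`` marking frames with degenerate (collinear) geometry.
    """
    try:
        fn = _PRIMITIVE_S[kind]
    except KeyError:
        raise PreconditionError(f"unknown primitive kind {kind!r}") from None
    return fn(p, idx)


def project_velocities(traj: Trajectory,
                       basis: list[LocalModeDefinition],
                       topology: Topology,
                       max_flagged: float = 0.01) -> ModeVelocitySeries:
    """Project Cartesian velocities onto local-mode velocities q̇_k(t).

    s-vectors are recomputed from the instantaneous geometry every frame.
    Frames where a bend or torsion becomes numerically collinear are flagged
    and their values linearly interpolated from neighbours; more than
    ``max_flagged`` (default 1 %) flagged frames raises an error.
    """
    if traj.velocities is None:
        raise PreconditionError(
            "trajectory has no velocities; run derive_velocities first")
    amap = np.asarray(topology.indices, dtype=np.intp)
    if amap.max() >= traj.n_atoms:
        raise PreconditionError("topology indices out of range")
    p = traj.positions[:, amap, :]
    v = traj.velocities[:, amap, :]
    F = p.shape[0]
    series = np.zeros((len(basis), F))
    flagged = np.zeros(F, dtype=bool)
    for k, mode in enumerate(basis):
        qdot = np.zeros(F)
        mode_flags = np.zeros(F, dtype=bool)
        for kind, idx, coeff in mode.primitives:
            svecs, flags = primitive_s_vectors(kind, p, idx)
            mode_flags |= flags
            for atom, s in svecs.items():
                qdot += coeff * np.sum(s * v[:, atom], axis=-1)
        if mode_flags.any():
            good = ~mode_flags
            if good.sum() < 2:
                raise PreconditionError(
                    f"mode {mode.name}: geometry degenerate in nearly all frames")
            qdot = qdot.copy()
            t = np.arange(F)
            qdot[mode_flags] = np.interp(t[mode_flags], t[good], qdot[good])
        flagged |= mode_flags
        series[k] = qdot
    frac = float(flagged.mean())
    if frac > max_flagged:
        raise PreconditionError(
            f"{100 * frac:.1f} % of frames have degenerate geometry "
            f"(limit {100 * max_flagged:.1f} %)")
    return ModeVelocitySeries(names=[m.name for m in basis], series=series,
                              timestep=traj.timestep, flagged_fraction=frac)


def bond_stretch_series(traj: Trajectory, i: int, j: int,
                        name: str = "nu(bond)") -> ModeVelocitySeries:
    """Single bond-stretch velocity ṙ_ij(t) = û_ij·(v_j − v_i).

    A convenience projection for diatomic-like fixtures (e.g. the Morse
    bond toy) that do not carry a full glycinate topology.
    """
    if traj.velocities is None:
        raise PreconditionError("trajectory has no velocities")
    d = traj.positions[:, j] - traj.positions[:, i]
    u = d / np.linalg.norm(d, axis=1, keepdims=True)
    qdot = np.sum(u * (traj.velocities[:, j] - traj.velocities[:, i]), axis=1)
    return ModeVelocitySeries(names=[name], series=qdot[None, :],
                              timestep=traj.timestep)


def local_mode_spectra(series: ModeVelocitySeries | list[ModeVelocitySeries],
                       window: str = "hann",
                       segments: int = 1) -> dict[str, Spectrum]:
    """Unit-area PSD of each local-mode velocity.

    When a list of series is given (one per molecule) the unit-area spectra
    are averaged mode-by-mode, which preserves the unit normalisation.
    """
    many = series if isinstance(series, list) else [series]
    if not many:
        raise PreconditionError("no series supplied")
    names = many[0].names
    out: dict[str, Spectrum] = {}
    for k, name in enumerate(names):
        specs = []
        for s in many:
            if s.names != names:
                raise PreconditionError("mode sets differ between molecules")
            q = s.series[k]
            if q.shape[0] < 2:
                raise PreconditionError("need at least 2 frames")
            if np.allclose(q, 0.0):
                raise PreconditionError(
                    f"mode {name}: all-zero series, normalisation undefined")
            specs.append(_unit_psd(q, s.timestep, window, segments))
        grid = specs[0].wavenumbers
        mean_int = np.mean([sp.intensity for sp in specs], axis=0)
        out[name] = Spectrum(wavenumbers=grid, intensity=mean_int,
                             normalization="unit_area", window=window,
                             metadata={"mode": name, "n_molecules": len(many)})
    return out


def _unit_psd(q: np.ndarray, dt: float, window: str, segments: int) -> Spectrum:
    from scipy import signal as _sig
    n = q.shape[0]
    win = "boxcar" if window in (None, "none") else window
    f, S = _sig.welch(q - q.mean(), fs=1.0 / dt, window=win,
                      nperseg=n // segments, noverlap=0, detrend=False,
                      scaling="density")
    spec = Spectrum(wavenumbers=f / C_CM_PER_FS, intensity=S * C_CM_PER_FS,
                    normalization="raw", window=window)
    return normalize_unit_area(spec)
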