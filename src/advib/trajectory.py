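"""Trajectory container and extended-XYZ input/output.

An MD trajectory is a fixed set of atoms observed at a fixed stride.  The
container keeps Cartesian positions (frames × atoms × 3, Å), optional
velocities (Å/fs), an optional fixed 3×3 cell (rows are lattice vectors, Å),
per-atom masses (amu) and the sampling time step (fs).

The only file format supported is the extended-XYZ dialect in which the
per-frame comment line carries ``Lattice="ax ay az bx by bz cx cy cz"`` and
``Properties=species:S:1:pos:R:3[:vel:R:3]`` — the lingua franca of MD
post-processing tools.
"""
from __future__ import annotations

import re
import shlex
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import (ElementError, EmptyTrajectoryError, FormatError,
                     PreconditionError)

__all__ = [
    "Trajectory",
    "AtomSelection",
    "atomic_mass",
    "read_trajectory",
    "write_trajectory",
    "trim_equilibration",
    "unwrap",
    "derive_velocities",
]


def atomic_mass(symbol: str) -> float:
    """Standard atomic weight (amu) for an element symbol.

    Raises
    ------
    ElementError
        If the symbol is not a known element.
    """
    el = gemmi.Element(symbol)
    if el.name.lower() != symbol.lower() or symbol.lower() == "x":
        raise ElementError(f"unknown element symbol {symbol!r}")
    return float(el.weight)


@dataclass
class Trajectory:
    """Time-ordered frames of an MD run with fixed atom set and stride."""

    species: list[str]
    positions: np.ndarray            # (n_frames, n_atoms, 3) Å
    timestep: float                  # fs
    masses: np.ndarray | None = None  # (n_atoms,) amu; filled from species
    velocities: np.ndarray | None = None  # (n_frames, n_atoms, 3) Å/fs
    cell: np.ndarray | None = None   # (3, 3) Å, rows are lattice vectors
    time_origin: float = 0.0         # fs

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise PreconditionError(
                f"positions must be (frames, atoms, 3), got {self.positions.shape}")
        if self.positions.shape[1] != len(self.species):
            raise PreconditionError("species length does not match positions")
        if not self.timestep > 0:
            raise PreconditionError("timestep must be positive")
        if self.masses is None:
            self.masses = np.array([atomic_mass(s) for s in self.species])
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (self.n_atoms,):
                raise PreconditionError("masses shape mismatch")
        if not np.all(self.masses > 0):
            raise PreconditionError("masses must be positive")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise PreconditionError("velocities shape mismatch")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float)
            if self.cell.shape != (3, 3):
                raise PreconditionError("cell must be 3x3")
            if abs(np.linalg.det(self.cell)) < 1e-12:
                raise PreconditionError("cell is singular")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        """Total simulated time span covered by the frames, fs."""
        return self.n_frames * self.timestep

    @property
    def times(self) -> np.ndarray:
        """Absolute time of each frame, fs."""
        return self.time_origin + self.timestep * np.arange(self.n_frames)

    def copy(self, **changes) -> "Trajectory":
        kw = dict(
            species=list(self.species),
            positions=self.positions.copy(),
            timestep=self.timestep,
            masses=self.masses.copy(),
            velocities=None if self.velocities is None else self.velocities.copy(),
            cell=None if self.cell is None else self.cell.copy(),
            time_origin=self.time_origin,
        )
        kw.update(changes)
        return Trajectory(**kw)


@dataclass(frozen=True)
class AtomSelection:
    """An ordered, duplicate-free group of atom indices with a label."""

    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise PreconditionError(f"duplicate indices in selection {self.label!r}")
        object.__setattr__(self, "indices", idx)

    def validate(self, n_atoms: int) -> None:
        bad = [i for i in self.indices if not 0 <= i < n_atoms]
        if bad:
            raise PreconditionError(
                f"selection {self.label!r} indices {bad} out of range [0, {n_atoms})")

    def asarray(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=np.intp)

    def __len__(self) -> int:
        return len(self.indices)


def full_selection(traj_or_n, label: str = "all") -> AtomSelection:
    """Selection covering every atom of a trajectory (or of ``n`` atoms)."""
    n = traj_or_n if isinstance(traj_or_n, int) else traj_or_n.n_atoms
    return AtomSelection(tuple(range(n)), label)


# ---------------------------------------------------------------------------
# extended-XYZ I/O
# ---------------------------------------------------------------------------

_PROPS_RE = re.compile(r"^[A-Za-z_]+:[SRIL]:\d+(:[A-Za-z_]+:[SRIL]:\d+)*$")


def _parse_comment(line: str) -> dict[str, str]:
    """Parse key=value tokens of an extxyz comment line (values may be quoted)."""
    out: dict[str, str] = {}
    try:
        tokens = shlex.split(line)
    except ValueError as exc:
        raise FormatError(f"unparsable comment line: {line!r}") from exc
    for tok in tokens:
        if "=" in tok:
            key, _, val = tok.partition("=")
            out[key] = val
    return out


def _parse_properties(props: str) -> list[tuple[str, str, int]]:
    if not _PROPS_RE.match(props):
        raise FormatError(f"unparsable Properties string: {props!r}")
    parts = props.split(":")
    return [(parts[i], parts[i + 1], int(parts[i + 2]))
            for i in range(0, len(parts), 3)]


def read_trajectory(path, format: str = "extxyz") -> Trajectory:
    """Read a trajectory from an extended-XYZ file.

    Velocities are populated only if a ``vel`` column is declared in the
    Properties string; masses are looked up from the standard atomic-weight
    table by element symbol.  The cell, if present, must be identical in
    every frame (fixed-cell dynamics only).

    The time step is taken from a ``timestep=<fs>`` comment-line key when
    present; otherwise it defaults to 1 fs and should be set by the caller.
    """
    if format != "extxyz":
        raise FormatError(f"unsupported trajectory format {format!r}")
    species: list[str] | None = None
    cell: np.ndarray | None = None
    timestep = None
    time_origin = 0.0
    frames_pos: list[np.ndarray] = []
    frames_vel: list[np.ndarray] = []
    has_vel: bool | None = None

    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    nframe = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(
                f"frame {nframe}: expected atom count, got {lines[i]!r}") from exc
        if i + 2 + natoms > len(lines):
            raise FormatError(f"frame {nframe}: truncated file")
        meta = _parse_comment(lines[i + 1])
        props = _parse_properties(meta.get("Properties", "species:S:1:pos:R:3"))
        if "Lattice" in meta:
            this_cell = np.fromstring(meta["Lattice"], sep=" ").reshape(3, 3)
            if cell is None:
                cell = this_cell
            elif not np.allclose(cell, this_cell, atol=1e-10):
                raise FormatError("varying cell across frames is not supported")
        if "timestep" in meta and timestep is None:
            timestep = float(meta["timestep"])
        if "time_origin" in meta and nframe == 0:
            time_origin = float(meta["time_origin"])

        cols: dict[str, slice] = {}
        start = 0
        for name, _kind, ncol in props:
            cols[name] = slice(start, start + ncol)
            start += ncol
        frame_species: list[str] = []
        pos = np.empty((natoms, 3))
        vel = np.empty((natoms, 3)) if "vel" in cols else None
        for a in range(natoms):
            fields = lines[i + 2 + a].split()
            if len(fields) < start:
                raise FormatError(f"frame {nframe}, atom {a}: too few columns")
            frame_species.append(fields[cols["species"]][0])
            pos[a] = [float(x) for x in fields[cols["pos"]]]
            if vel is not None:
                vel[a] = [float(x) for x in fields[cols["vel"]]]
        if species is None:
            species = frame_species
            has_vel = vel is not None
        else:
            if len(frame_species) != len(species):
                raise FormatError(
                    f"frame {nframe}: atom count {len(frame_species)} differs "
                    f"from first frame ({len(species)})")
            if frame_species != species:
                raise FormatError(f"frame {nframe}: atom ordering/species changed")
            if (vel is not None) != has_vel:
                raise FormatError(f"frame {nframe}: velocity columns inconsistent")
        frames_pos.append(pos)
        if vel is not None:
            frames_vel.append(vel)
        i += 2 + natoms
        nframe += 1

    if species is None:
        raise FormatError("no frames in file")
    return Trajectory(
        species=species,
        positions=np.stack(frames_pos),
        velocities=np.stack(frames_vel) if frames_vel else None,
        cell=cell,
        timestep=1.0 if timestep is None else timestep,
        time_origin=time_origin,
    )


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as extended-XYZ (positions, optional velocities)."""
    props = "species:S:1:pos:R:3"
    if traj.velocities is not None:
        props += ":vel:R:3"
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            comment = [f"Properties={props}"]
            if traj.cell is not None:
                latt = " ".join(f"{x:.10f}" for x in traj.cell.ravel())
                comment.append(f'Lattice="{latt}"')
            comment.append(f"timestep={traj.timestep:.10g}")
            if f == 0:
                comment.append(f"time_origin={traj.time_origin:.10g}")
            fh.write(" ".join(comment) + "\n")
            for a in range(traj.n_atoms):
                row = [f"{traj.species[a]:<2s}"]
                row += [f"{x: .10e}" for x in traj.positions[f, a]]
                if traj.velocities is not None:
                    row += [f"{x: .10e}" for x in traj.velocities[f, a]]
                fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# preparation operations
# ---------------------------------------------------------------------------

def trim_equilibration(traj: Trajectory, t_equil: float) -> Trajectory:
    """Drop all frames earlier than ``t_equil`` fs after the time origin.

    Mirrors the standard practice of discarding an initial equilibration
    period (e.g. 1 ps) whose motion is biased by the starting geometry.
    """
    if t_equil < 0:
        raise PreconditionError("t_equil must be non-negative")
    if t_equil == 0:
        return traj.copy()
    n_drop = int(np.ceil(t_equil / traj.timestep - 1e-12))
    if n_drop >= traj.n_frames:
        raise EmptyTrajectoryError(
            f"t_equil={t_equil} fs leaves no frames "
            f"(duration {traj.duration} fs)")
    return traj.copy(
        positions=traj.positions[n_drop:].copy(),
        velocities=None if traj.velocities is None
        else traj.velocities[n_drop:].copy(),
        time_origin=traj.time_origin + n_drop * traj.timestep,
    )


def unwrap(traj: Trajectory) -> Trajectory:
    """Remove periodic-image jumps so consecutive displacements are minimal.

    The first frame is kept as-is; each subsequent frame is shifted by whole
    lattice vectors so that every atom's frame-to-frame displacement is the
    minimum-image displacement.  Required before any time averaging of
    positions under periodic boundary conditions.
    """
    if traj.cell is None:
        raise PreconditionError("unwrap requires a cell")
    inv = np.linalg.inv(traj.cell)
    frac = traj.positions @ inv              # (F, N, 3) fractional
    dfrac = np.diff(frac, axis=0)
    dfrac -= np.round(dfrac)
    unwrapped_frac = np.concatenate(
        [frac[:1], frac[:1] + np.cumsum(dfrac, axis=0)])
    return traj.copy(positions=unwrapped_frac @ traj.cell)


def derive_velocities(traj: Trajectory, overwrite: bool = False) -> Trajectory:
    """Fill velocities by central differences of (unwrapped) positions.

    v(t) = [x(t+Δt) − x(t−Δt)] / (2Δt); the two endpoint frames, where no
    centred stencil exists, are dropped.  Exact for positions affine in time.
    Existing velocities are kept unless ``overwrite`` is set.
    """
    if traj.velocities is not None and not overwrite:
        return traj.copy()
    if traj.n_frames < 3:
        raise PreconditionError("central differences need at least 3 frames")
    v = (traj.positions[2:] - traj.positions[:-2]) / (2.0 * traj.timestep)
    return traj.copy(
        positions=traj.positions[1:-1].copy(),
        velocities=v,
        time_origin=traj.time_origin + traj.timestep,
    )
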