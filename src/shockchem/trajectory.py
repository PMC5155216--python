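"""Domain types and extended-XYZ I/O for atomistic trajectories.

The trajectory container is array-backed: one element array shared by all
frames plus ``(n_frames, n_atoms, 3)`` position stacks, which keeps the
bond-network analysis vectorizable.  Coordinates are stored Cartesian and
wrapped into the cell on ingest; an unwrapped copy is retained because
wrapping destroys displacement statistics (mean-squared displacements).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .units import G_CM3_PER_AMU_A3, mass_of


class TrajectoryError(ValueError):
    """Malformed trajectory file or inconsistent frame structure."""


@dataclass(frozen=True)
class SimulationCell:
    """Periodic simulation cell; columns of ``h`` are the lattice vectors."""

    h: np.ndarray
    pbc: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        if h.shape != (3, 3):
            raise ValueError("cell matrix must be 3x3")
        if np.linalg.det(h) <= 0:
            raise ValueError("cell volume det(h) must be positive")
        object.__setattr__(self, "h", h)

    @classmethod
    def orthorhombic(cls, lx: float, ly: float, lz: float,
                     pbc: tuple[bool, bool, bool] = (True, True, True)) -> "SimulationCell":
        return cls(np.diag([lx, ly, lz]).astype(float), pbc)

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.h))

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.h, axis=0)

    def cart_to_frac(self, pos: np.ndarray) -> np.ndarray:
        return np.asarray(pos, float) @ np.linalg.inv(self.h).T

    def frac_to_cart(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, float) @ self.h.T

    def wrap(self, pos: np.ndarray) -> np.ndarray:
        frac = self.cart_to_frac(pos)
        for ax, per in enumerate(self.pbc):
            if per:
                frac[..., ax] %= 1.0
        return self.frac_to_cart(frac)

    def minimum_image(self, disp: np.ndarray) -> np.ndarray:
        """Minimum-image displacement vector(s) for Cartesian *disp*.

        Orthorhombic cells use the nearest-fractional-image convention
        directly; skewed cells additionally refine over the 3³
        neighbouring images, which that convention alone can miss.
        """
        frac = self.cart_to_frac(disp)
        for ax, per in enumerate(self.pbc):
            if per:
                frac[..., ax] -= np.round(frac[..., ax])
        d = self.frac_to_cart(frac)
        if np.allclose(self.h, np.diag(np.diag(self.h))):
            return d
        shifts = self.frac_to_cart(np.array(
            [[i, j, k]
             for i in ((-1, 0, 1) if self.pbc[0] else (0,))
             for j in ((-1, 0, 1) if self.pbc[1] else (0,))
             for k in ((-1, 0, 1) if self.pbc[2] else (0,))], dtype=float))
        cand = d[..., None, :] + shifts          # (..., n_img, 3)
        best = np.argmin((cand ** 2).sum(axis=-1), axis=-1)
        return np.take_along_axis(
            cand, best[..., None, None], axis=-2).squeeze(-2)


@dataclass
class Frame:
    """A single snapshot: element labels, Cartesian positions, cell, time."""

    elements: np.ndarray
    positions: np.ndarray
    cell: SimulationCell
    time: float = 0.0
    velocities: np.ndarray | None = None
    unwrapped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype="U2")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.elements), 3):
            raise ValueError("positions must be (n_atoms, 3)")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def composition(self) -> dict[str, int]:
        return dict(Counter(self.elements.tolist()))

    def masses(self) -> np.ndarray:
        return np.array([mass_of(e) for e in self.elements])


def minimum_image_distance(frame: Frame, i: int, j: int) -> float:
    """Shortest periodic distance between atoms *i* and *j* in Å."""
    if i == j:
        raise ValueError("minimum_image_distance requires two distinct atoms")
    d = frame.positions[j] - frame.positions[i]
    return float(np.linalg.norm(frame.cell.minimum_image(d)))


def initial_density(composition: Mapping[str, int], cell: SimulationCell) -> float:
    """Mass density rho0 = sum(m_i)/V in g/cm³ from a composition census."""
    if not composition or sum(composition.values()) == 0:
        raise ValueError("empty composition")
    total_amu = sum(mass_of(el) * n for el, n in composition.items())
    return total_amu / cell.volume * G_CM3_PER_AMU_A3


class Trajectory:
    """Ordered frames with a shared atom list and uniform timestep."""

    def __init__(
        self,
        elements: Sequence[str],
        times: np.ndarray,
        positions: np.ndarray,
        cells: Sequence[SimulationCell] | np.ndarray,
        velocities: np.ndarray | None = None,
        unwrapped: np.ndarray | None = None,
        metadata: dict | None = None,
        wrap: bool = True,
    ) -> None:
        self.elements = np.asarray(elements, dtype="U2")
        self.times = np.asarray(times, dtype=float)
        positions = np.asarray(positions, dtype=float)
        n_frames, n_atoms = positions.shape[:2]
        if n_atoms != len(self.elements):
            raise TrajectoryError("positions second axis must match element count")
        if len(self.times) != n_frames:
            raise TrajectoryError("times length must match frame count")
        if n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("frame times must be strictly increasing")
        if isinstance(cells, np.ndarray) and cells.ndim == 3:
            cells = [SimulationCell(h) for h in cells]
        self.cells: list[SimulationCell] = list(cells)
        if len(self.cells) != n_frames:
            raise TrajectoryError("one cell per frame required")
        self.unwrapped = None if unwrapped is None else np.asarray(unwrapped, float)
        if wrap:
            if self.unwrapped is None:
                self.unwrapped = positions.copy()
            positions = np.stack(
                [c.wrap(p) for c, p in zip(self.cells, positions)])
        self.positions = positions
        self.velocities = None if velocities is None else np.asarray(velocities, float)
        self.metadata = dict(metadata or {})

    # -- container protocol --------------------------------------------
    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self) -> Iterator[Frame]:
        return (self.frame(i) for i in range(len(self)))

    def frame(self, i: int) -> Frame:
        return Frame(
            elements=self.elements,
            positions=self.positions[i],
            cell=self.cells[i],
            time=float(self.times[i]),
            velocities=None if self.velocities is None else self.velocities[i],
            unwrapped=None if self.unwrapped is None else self.unwrapped[i],
        )

    @classmethod
    def from_frames(cls, frames: Sequence[Frame], metadata: dict | None = None,
                    wrap: bool = True) -> "Trajectory":
        if not frames:
            raise TrajectoryError("empty trajectory")
        f0 = frames[0]
        for k, f in enumerate(frames):
            if f.n_atoms != f0.n_atoms or not np.all(f.elements == f0.elements):
                raise TrajectoryError(f"frame {k}: atom list differs from frame 0")
        vel = None
        if all(f.velocities is not None for f in frames):
            vel = np.stack([f.velocities for f in frames])
        unw = None
        if all(f.unwrapped is not None for f in frames):
            unw = np.stack([f.unwrapped for f in frames])
        return cls(
            elements=f0.elements,
            times=np.array([f.time for f in frames]),
            positions=np.stack([f.positions for f in frames]),
            cells=[f.cell for f in frames],
            velocities=vel,
            unwrapped=unw,
            metadata=metadata,
            wrap=wrap,
        )

    # -- derived quantities --------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def dt(self) -> float:
        """Uniform timestep in fs; raises if the spacing is not constant."""
        if len(self) < 2:
            raise TrajectoryError("timestep undefined for a single frame")
        diffs = np.diff(self.times)
        dt = diffs[0]
        if np.any(np.abs(diffs - dt) > 1e-9 * abs(dt)):
            raise TrajectoryError("frame times are not uniformly spaced")
        return float(dt)

    def composition(self) -> dict[str, int]:
        return dict(Counter(self.elements.tolist()))

    def displacement_source(self) -> np.ndarray:
        """Coordinates suitable for displacement statistics (unwrapped)."""
        return self.unwrapped if self.unwrapped is not None else self.positions


# ---------------------------------------------------------------------------
# Extended XYZ I/O
#
# Dialect: per-frame comment line carrying a row-major Lattice="..." record
# (rows are lattice vectors) and Properties=species:S:1:pos:R:3[:vel:R:3],
# plus Time=<fs>.
# ---------------------------------------------------------------------------

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r'Time=([-+0-9.eE]+)')
_PROPS_RE = re.compile(r'Properties=(\S+)')


def write_extxyz(path, trajectory: Trajectory) -> None:
    """Write *trajectory* to extended XYZ at *path*."""
    coords = trajectory.displacement_source()
    with open(path, "w") as fh:
        for k in range(len(trajectory)):
            cell = trajectory.cells[k]
            lat = " ".join(f"{x:.10g}" for x in cell.h.T.ravel())
            props = "species:S:1:pos:R:3"
            if trajectory.velocities is not None:
                props += ":vel:R:3"
            fh.write(f"{trajectory.n_atoms}\n")
            fh.write(f'Lattice="{lat}" Properties={props} '
                     f"Time={trajectory.times[k]:.10g}\n")
            for a in range(trajectory.n_atoms):
                row = f"{trajectory.elements[a]:<2s} " + " ".join(
                    f"{x:.8f}" for x in coords[k, a])
                if trajectory.velocities is not None:
                    row += " " + " ".join(
                        f"{v:.8f}" for v in trajectory.velocities[k, a])
                fh.write(row + "\n")


def read_extxyz(path) -> Trajectory:
    """Parse an extended-XYZ file into a :class:`Trajectory`.

    Positions are wrapped into the cell; the file's coordinates are kept as
    the unwrapped copy.  Raises :class:`TrajectoryError` naming the frame
    index on malformed headers or truncated/inconsistent frames.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[Frame] = []
    pos = 0
    k = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError:
            raise TrajectoryError(
                f"frame {k}: expected atom count, got {lines[pos]!r}") from None
        if pos + 1 >= len(lines):
            raise TrajectoryError(f"frame {k}: missing comment line")
        comment = lines[pos + 1]
        m = _LATTICE_RE.search(comment)
        if not m:
            raise TrajectoryError(f"frame {k}: no Lattice record in header")
        lat = np.fromstring(m.group(1), sep=" ")
        if lat.size != 9:
            raise TrajectoryError(f"frame {k}: Lattice needs 9 numbers")
        cell = SimulationCell(lat.reshape(3, 3).T)
        tm = _TIME_RE.search(comment)
        time = float(tm.group(1)) if tm else float(k)
        pm = _PROPS_RE.search(comment)
        has_vel = bool(pm and ":vel:R:3" in pm.group(1))
        body = lines[pos + 2: pos + 2 + n_atoms]
        if len(body) < n_atoms:
            raise TrajectoryError(f"frame {k}: truncated (expected {n_atoms} atoms)")
        elements, xyz, vel = [], [], []
        for a, row in enumerate(body):
            parts = row.split()
            need = 7 if has_vel else 4
            if len(parts) < need:
                raise TrajectoryError(f"frame {k}: atom line {a} malformed")
            elements.append(parts[0])
            xyz.append([float(x) for x in parts[1:4]])
            if has_vel:
                vel.append([float(x) for x in parts[4:7]])
        frames.append(Frame(
            elements=np.array(elements),
            positions=np.array(xyz),
            cell=cell,
            time=time,
            velocities=np.array(vel) if has_vel else None,
            unwrapped=np.array(xyz),
        ))
        pos += 2 + n_atoms
        k += 1
    if not frames:
        raise TrajectoryError("file contains no frames")
    return Trajectory.from_frames(frames)
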