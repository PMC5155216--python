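"""Synthetic trajectory generators.

Every input the analysis pipeline needs is generated here, with
controlled randomness:

* a 182-atom Fe36 / 16 N2 / 38 H2O supercell (29.72 × 8.580 × 8.580 Å)
  mimicking the shocked iron-slab-in-ocean system;
* scripted reactive trajectories in which proton transfers, N-N
  scissions, adsorptions and protonations happen at prescribed times by
  geometric relocation (chemistry is encoded purely by distances versus
  bond cutoffs — there is no electronic structure here, and the scripted
  fixtures exist to exercise the analyzers, not to model dynamics);
* Brownian trajectories with a known diffusion coefficient, for testing
  the MSD/Einstein estimator;
* analytic shock-profile tables consistent with the jump conditions;
* Lennard-Jones crystals for the dynamics engines.

Scripted fixtures carry per-frame Gaussian positional jitter.  Baseline
geometries keep every unintended pair distance away from its bond cutoff
by a safety band, so transient jitter excursions can never satisfy the
bond *lifetime* criterion (which is exactly the robustness that
criterion provides in the real analysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .kinetics import hugoniot_jump
from .potentials import PairPotential, PairTerm, Potential
from .reactive import BondCriteria, pair_key
from .trajectory import Frame, SimulationCell, Trajectory
from .units import CM2_S_TO_A2_FS

#: cell of the reference shocked system, Å
SYSTEM_CELL = (29.72, 8.580, 8.580)
#: printed first-appearance times of the three NH3 molecules, ps
DEFAULT_FORMATION_TIMES_PS = (1.343, 2.044, 3.674)

_WATER_H_OFFSETS = np.array([  # O-H 0.96 Å, H-O-H 104.5°, both H toward +z
    [0.0, 0.96 * math.sin(math.radians(52.25)), 0.96 * math.cos(math.radians(52.25))],
    [0.0, -0.96 * math.sin(math.radians(52.25)), 0.96 * math.cos(math.radians(52.25))],
])
_N2_HALF_BOND = 0.55           # N2 bond length 1.10 Å, oriented along x


class ScriptError(ValueError):
    """A scripted event is geometrically impossible or ambiguous."""


# ---------------------------------------------------------------------------
# initial system
# ---------------------------------------------------------------------------

@dataclass
class SystemInfo:
    """Atom bookkeeping for the generated Fe/N2/H2O system."""

    fe: list[int]
    n2: list[tuple[int, int]]          # (x-minus N, x-plus N) per molecule
    waters: list[tuple[int, int, int]]  # (O, H1, H2) per molecule


def build_initial_system(seed: int = 0, jitter: float = 0.02) -> Frame:
    """182-atom frame: bcc Fe36 slab centered in x, surrounded by 38 H2O
    with 16 N2 substituted at random interior water sites (seeded)."""
    frame, _ = build_initial_system_info(seed=seed, jitter=jitter)
    return frame


def build_initial_system_info(seed: int = 0,
                              jitter: float = 0.02) -> tuple[Frame, SystemInfo]:
    rng = np.random.default_rng(seed)
    lx, ly, lz = SYSTEM_CELL
    cell = SimulationCell.orthorhombic(lx, ly, lz)
    a = ly / 3.0                      # bcc Fe lattice parameter, 2.86 Å
    x0 = lx / 2.0 - 0.75 * a          # slab occupies [x0, x0 + 1.5a]

    elements: list[str] = []
    positions: list[np.ndarray] = []

    def add(el, pos):
        elements.append(el)
        positions.append(np.asarray(pos, float))
        return len(elements) - 1

    # Fe slab: 2x3x3 bcc cells, periodic in y and z
    fe_idx = []
    for cx in range(2):
        for cy in range(3):
            for cz in range(3):
                fe_idx.append(add("Fe", [x0 + cx * a, (cy + 0.25) * a,
                                         (cz + 0.25) * a]))
                fe_idx.append(add("Fe", [x0 + (cx + 0.5) * a,
                                         (cy + 0.75) * a, (cz + 0.75) * a]))

    # molecule lattice: 6 x-columns x 3x3 (y,z) sites
    margin_cols = [lx * 1.5 / 29.72, lx * 28.0 / 29.72]
    interior_cols = [5.05, 8.6, lx - 8.82, lx - 5.27]
    cols = sorted([margin_cols[0], *interior_cols, margin_cols[1]])
    yz = [(cy + 0.5) * a for cy in range(3)]
    sites = [(cx, y, z) for cx in cols for y in yz for z in yz]
    interior_sites = [s for s in sites if s[0] in interior_cols]
    n2_sites = set(map(tuple, rng.choice(
        np.array(interior_sites), size=16, replace=False)))

    n2_list: list[tuple[int, int]] = []
    water_list: list[tuple[int, int, int]] = []
    for site in sites:
        c = np.array(site)
        if tuple(site) in n2_sites:
            i0 = add("N", c - [_N2_HALF_BOND, 0, 0])
            i1 = add("N", c + [_N2_HALF_BOND, 0, 0])
            n2_list.append((i0, i1))
        else:
            o = add("O", c)
            h1 = add("H", c + _WATER_H_OFFSETS[0])
            h2 = add("H", c + _WATER_H_OFFSETS[1])
            water_list.append((o, h1, h2))

    pos = np.array(positions)
    if jitter > 0:
        pos = pos + rng.normal(scale=jitter, size=pos.shape)
    frame = Frame(np.array(elements), pos, cell, time=0.0, unwrapped=pos.copy())
    return frame, SystemInfo(fe=fe_idx, n2=n2_list, waters=water_list)


# ---------------------------------------------------------------------------
# event scripts
# ---------------------------------------------------------------------------

EVENT_KINDS = ("proton_transfer", "bond_scission", "adsorption", "protonation")


@dataclass
class Event:
    """One scripted relocation.

    ``time`` is the instant the bond-graph change registers under the
    default lifetime criterion: bond-forming kinds are applied L-1
    frames early so the new bond completes its lifetime window exactly
    at ``time``; scissions are applied at ``time`` (a bond drops the
    moment its distance exceeds the cutoff).

    The destination of the moved atom (``atoms[0]``) is either absolute
    (``dest``) or relative to a target atom (``atoms[1]``) via
    ``distance`` along ``direction``.
    """

    time: float                       # fs
    kind: str
    atoms: tuple[int, ...]
    distance: float | None = None     # Å
    direction: tuple[float, float, float] | None = None
    dest: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ScriptError(f"unknown event kind {self.kind!r}")


@dataclass
class EventScript:
    """Ordered scripted events plus background jitter settings."""

    events: list[Event] = field(default_factory=list)
    jitter: float = 0.05              # Å, per-frame Gaussian amplitude
    seed: int = 0

    def sorted_events(self) -> list[Event]:
        return sorted(self.events, key=lambda e: e.time)

    # --- plain-text (YAML) serialization -------------------------------
    def to_dict(self) -> dict:
        return {
            "jitter": self.jitter,
            "seed": self.seed,
            "events": [
                {k: v for k, v in {
                    "time": float(e.time), "kind": e.kind,
                    "atoms": [int(a) for a in e.atoms],
                    "distance": None if e.distance is None else float(e.distance),
                    "direction": None if e.direction is None
                    else [float(x) for x in e.direction],
                    "dest": None if e.dest is None
                    else [float(x) for x in e.dest],
                }.items() if v is not None}
                for e in self.events],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventScript":
        events = [Event(
            time=float(e["time"]), kind=e["kind"], atoms=tuple(e["atoms"]),
            distance=e.get("distance"),
            direction=tuple(e["direction"]) if e.get("direction") else None,
            dest=tuple(e["dest"]) if e.get("dest") else None,
        ) for e in d.get("events", [])]
        return cls(events=events, jitter=float(d.get("jitter", 0.05)),
                   seed=int(d.get("seed", 0)))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "EventScript":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


MIN_PAIR_DISTANCE = 0.7
#: half-width of the forbidden band around each cutoff for scripted
#: baseline geometry: pair distances must sit clearly inside or clearly
#: outside every cutoff so jitter cannot sustain an unintended bond
CUTOFF_SAFETY_BAND = 0.12


def _placement_ok(dest: np.ndarray, moved_element: str, base: np.ndarray,
                  elements: np.ndarray, cell: SimulationCell,
                  cutoffs, band: float,
                  skip: frozenset[int] | set[int] = frozenset()) -> bool:
    """True if *dest* clashes with nothing and every cutoff-carrying pair
    distance falls clearly inside or clearly outside its cutoff."""
    d = np.linalg.norm(cell.minimum_image(base - dest), axis=1)
    for a in range(len(base)):
        if a in skip:
            continue
        if d[a] < MIN_PAIR_DISTANCE:
            return False
        c = cutoffs.get(pair_key(moved_element, elements[a]))
        if c is not None and (c - band) < d[a] < (c + band):
            return False
    return True


def script_reactive_trajectory(
    initial_frame: Frame,
    script: EventScript,
    duration: float = 4000.0,
    dt: float = 0.242,
    criteria: BondCriteria | None = None,
) -> Trajectory:
    """Deterministic scripted trajectory from an event script.

    Atoms sit at their baseline positions plus per-frame Gaussian jitter;
    each event instantaneously relocates its moved atom, timed so the
    bond-graph change registers exactly at the event's nominal time
    under *criteria* (default: 2.42 fs lifetime at a 0.242 fs step).
    Raises :class:`ScriptError` for geometrically impossible events.
    """
    criteria = criteria or BondCriteria()
    L = criteria.frames_required(dt)
    n_steps = int(round(duration / dt))
    n_frames = n_steps + 1
    cell = initial_frame.cell
    elements = initial_frame.elements
    base = initial_frame.positions.copy()
    rng = np.random.default_rng(script.seed)

    applications: list[tuple[int, int, Event]] = []
    for k, ev in enumerate(script.sorted_events()):
        f_nominal = int(round(ev.time / dt))
        if not 0 <= f_nominal <= n_steps:
            raise ScriptError(f"event {k}: time {ev.time} fs outside trajectory")
        f_apply = f_nominal if ev.kind == "bond_scission" else f_nominal - (L - 1)
        if f_apply < 0:
            raise ScriptError(f"event {k}: bond-forming event at {ev.time} fs "
                              f"needs {L - 1} preceding frames")
        applications.append((f_apply, k, ev))
    applications.sort(key=lambda t: (t[0], t[1]))

    positions = np.empty((n_frames, len(base), 3))
    prev = 0
    for f_apply, k, ev in applications:
        if f_apply > prev:
            positions[prev:f_apply] = base
        moved = ev.atoms[0]
        if ev.dest is not None:
            dest = np.asarray(ev.dest, float)
        else:
            if ev.distance is None or ev.direction is None or len(ev.atoms) < 2:
                raise ScriptError(
                    f"event {k} ({ev.kind} at {ev.time} fs): needs dest, or "
                    "a target atom with distance and direction")
            u = np.asarray(ev.direction, float)
            u = u / np.linalg.norm(u)
            dest = base[ev.atoms[1]] + ev.distance * u
        if not _placement_ok(dest, elements[moved], base, elements, cell,
                             criteria.cutoffs, CUTOFF_SAFETY_BAND,
                             skip={moved}):
            raise ScriptError(
                f"event {k} ({ev.kind} at {ev.time} fs): destination clashes "
                "or sits within the ambiguity band of a bond cutoff")
        base = base.copy()
        base[moved] = dest
        prev = f_apply
    positions[prev:] = base

    if script.jitter > 0:
        positions += rng.normal(scale=script.jitter, size=positions.shape)
    times = np.arange(n_frames) * dt
    return Trajectory(elements, times, positions, [cell] * n_frames,
                      metadata={"script": script.to_dict(), "dt": dt})


def validate_script_trajectory(traj: Trajectory, script: EventScript,
                               criteria: BondCriteria | None = None) -> None:
    """Re-analyze the scripted pairs: each event's intended bond delta
    must register at exactly the scripted frame.  Raises AssertionError
    on mismatch (generator self-check)."""
    criteria = criteria or BondCriteria()
    dt = traj.dt
    L = criteria.frames_required(dt)
    for k, ev in enumerate(script.sorted_events()):
        if len(ev.atoms) < 2:
            continue
        i, j = ev.atoms[0], ev.atoms[1]
        cutoff = criteria.cutoffs.get(pair_key(traj.elements[i], traj.elements[j]))
        if cutoff is None:
            continue
        f = int(round(ev.time / dt))
        d = np.linalg.norm([traj.cells[f].minimum_image(
            traj.positions[g, j] - traj.positions[g, i])
            for g in range(max(f - L, 0), f + 1)], axis=1)
        if ev.kind == "bond_scission":
            if not (np.all(d[:-1] <= cutoff) and d[-1] > cutoff):
                raise AssertionError(
                    f"event {k}: scission of pair ({i},{j}) did not register "
                    f"at frame {f}")
        else:
            if not np.all(d[-L:] <= cutoff) or (f - L >= 0 and d[0] <= cutoff):
                raise AssertionError(
                    f"event {k}: bond ({i},{j}) lifetime window does not "
                    f"complete at frame {f}")


# ---------------------------------------------------------------------------
# the reference scripted story: three NH3 formations
# ---------------------------------------------------------------------------

def nh3_formation_script(
    frame: Frame,
    info: SystemInfo,
    times_ps: Sequence[float] = DEFAULT_FORMATION_TIMES_PS,
    protonate: bool = True,
    jitter: float = 0.05,
    seed: int = 7,
    dt: float = 0.242,
) -> EventScript:
    """Build an event script producing NH3 at the given times.

    Each formation hydrogenates one N of an N2 molecule with three H
    atoms taken from distant waters (arriving 600/400/200 fs before the
    nominal time), then dissociates the N-N bond at the nominal time by
    relocating the partner N onto an iron-slab surface site (the N-Fe
    contact preceding N-N scission mirrors the associative reduction
    pathway).  With ``protonate`` the fresh NH3 receives a fourth H
    50 fs later, becoming NH4 without incrementing the cumulative count.

    Because formations overlap in time, every planned destination is
    checked against each atom's full position *timeline* (original and
    relocated positions, with the exact application frames used by
    :func:`script_reactive_trajectory`), so interleaved events cannot
    clash.
    """
    criteria = BondCriteria()
    L = criteria.frames_required(dt)
    cell = frame.cell
    elements = frame.elements
    lx = cell.h[0, 0]
    band = CUTOFF_SAFETY_BAND
    events: list[Event] = []
    used_n2: set[int] = set()
    used_h: set[int] = set()

    # per-atom position timeline: list of (apply_frame, position)
    timeline: dict[int, list[tuple[int, np.ndarray]]] = {
        a: [(0, frame.positions[a])] for a in range(frame.n_atoms)}

    def apply_frame_of(time_fs: float, kind: str) -> int:
        f = int(round(time_fs / dt))
        return f if kind == "bond_scission" else f - (L - 1)

    def positions_from(atom: int, fa: int) -> list[np.ndarray]:
        segs = timeline[atom]
        out = []
        for k, (start, pos) in enumerate(segs):
            end = segs[k + 1][0] if k + 1 < len(segs) else None
            if end is None or end > fa:
                out.append(pos)
        return out

    def dest_ok(dest: np.ndarray, el: str, fa: int,
                allow: set[int] = frozenset()) -> bool:
        # atoms in *allow* are intended bond partners (distance only has
        # to respect the hard floor); every other atom must stay clearly
        # outside its cutoff so no unintended bond can form
        for a in range(frame.n_atoms):
            c = criteria.cutoffs.get(pair_key(el, elements[a]))
            for pos in positions_from(a, fa):
                d = float(np.linalg.norm(cell.minimum_image(pos - dest)))
                if d < MIN_PAIR_DISTANCE:
                    return False
                if a not in allow and c is not None and d < (c + band):
                    return False
        return True

    def relocate(atom: int, dest: np.ndarray, fa: int) -> None:
        timeline[atom].append((fa, np.asarray(dest, float)))

    def current_pos(atom: int) -> np.ndarray:
        return timeline[atom][-1][1]

    fe_x = np.array([current_pos(i)[0] for i in info.fe])
    left_anchors = [i for i in info.fe
                    if abs(current_pos(i)[0] - fe_x.min()) < 0.1]
    right_anchors = [i for i in info.fe
                     if abs(current_pos(i)[0] - fe_x.max()) < 0.1]

    def water_h_donors(na: int, count: int) -> list[int]:
        # farthest unused water hydrogens, so donor remnants stay clear
        cands = [(float(np.linalg.norm(cell.minimum_image(
            current_pos(o) - current_pos(na)))), h1, h2)
            for (o, h1, h2) in info.waters]
        cands.sort(reverse=True)
        out = []
        for _, h1, h2 in cands:
            for h in (h1, h2):
                if h not in used_h:
                    out.append(h)
                    break
            if len(out) == count:
                return out
        raise ScriptError("not enough unused water hydrogens")

    for t_ps in times_ps:
        t = t_ps * 1000.0
        placed = False
        for mol_k, (n_minus, n_plus) in enumerate(info.n2):
            if mol_k in used_n2:
                continue
            na, nb = n_plus, n_minus
            na_pos = current_pos(na)
            h_frames = [apply_frame_of(t - 600.0 + 200.0 * m,
                                       "proton_transfer") for m in range(3)]
            if h_frames[0] < 0:
                raise ScriptError(f"formation at {t_ps} ps starts before t=0")
            # three H's at 1.0 Å from na, 120° apart in the y-z plane;
            # scan the rotation offset until all three sites stay clear
            dirs = None
            for phi0 in range(0, 120, 5):
                cand = [np.array([0.0,
                                  math.cos(math.radians(phi0 + 120 * m)),
                                  math.sin(math.radians(phi0 + 120 * m))])
                        for m in range(3)]
                if all(dest_ok(na_pos + 1.0 * u, "H", fa, allow={na, nb})
                       for u, fa in zip(cand, h_frames)):
                    dirs = cand
                    break
            if dirs is None:
                continue
            # park nb 1.7 Å off a slab-surface Fe on the side opposite na,
            # so the scission registers and nb leaves as an N-Fe adsorbate
            on_left = na_pos[0] < lx / 2
            anchors = right_anchors if on_left else left_anchors
            sign = 1.0 if on_left else -1.0
            f_park = apply_frame_of(t, "bond_scission")
            park = None
            for fe in anchors:
                dest = current_pos(fe) + np.array([sign * 1.7, 0.0, 0.0])
                if dest_ok(dest, "N", f_park, allow={fe}):
                    park = dest
                    break
            if park is None:
                continue
            hs = water_h_donors(na, 3)
            for m, (h, u, fa) in enumerate(zip(hs, dirs, h_frames)):
                events.append(Event(time=t - 600.0 + 200.0 * m,
                                    kind="proton_transfer", atoms=(h, na),
                                    distance=1.0, direction=tuple(u)))
                relocate(h, na_pos + 1.0 * u, fa)
                used_h.add(h)
            events.append(Event(time=t, kind="bond_scission", atoms=(nb, na),
                                dest=tuple(park)))
            relocate(nb, park, f_park)
            if protonate:
                h4 = water_h_donors(na, 1)[0]
                u4 = np.array([-1.0, 0.0, 0.0])   # nb's vacated site
                dest4 = na_pos + 1.0 * u4
                f4 = apply_frame_of(t + 50.0, "protonation")
                if not dest_ok(dest4, "H", f4, allow={na}):
                    raise ScriptError(f"protonation site blocked near atom {na}")
                events.append(Event(time=t + 50.0, kind="protonation",
                                    atoms=(h4, na), distance=1.0,
                                    direction=tuple(u4)))
                relocate(h4, dest4, f4)
                used_h.add(h4)
            used_n2.add(mol_k)
            placed = True
            break
        if not placed:
            raise ScriptError(f"no N2 molecule admits an NH3 formation at "
                              f"{t_ps} ps")
    return EventScript(events=events, jitter=jitter, seed=seed)


# ---------------------------------------------------------------------------
# bond-inventory fixture
# ---------------------------------------------------------------------------

DEFAULT_INVENTORY = {
    pair_key("H", "O"): 43,
    pair_key("O", "Fe"): 47,
    pair_key("H", "N"): 24,
    pair_key("H", "Fe"): 18,
}


def bond_inventory_fixture(
    counts: dict | None = None,
    duration: float = 4000.0,
    dt: float = 0.242,
    jitter: float = 0.02,
    seed: int = 3,
    spacing: float = 6.0,
) -> Trajectory:
    """Trajectory of isolated bonded pairs realizing an exact bond census.

    Each requested bond is one well-separated atom pair held at 80 % of
    its cutoff distance for the whole run, so after the lifetime window
    completes the per-type counts equal *counts* at every later frame
    (in particular at 4 ps).
    """
    criteria = BondCriteria()
    counts = DEFAULT_INVENTORY if counts is None else {
        pair_key(*k): v for k, v in counts.items()}
    pairs: list[tuple[str, str, float]] = []
    for (a, b), n in counts.items():
        cutoff = criteria.cutoffs[pair_key(a, b)]
        pairs.extend([(a, b, 0.8 * cutoff)] * n)
    n_pairs = len(pairs)
    per_axis = int(np.ceil(n_pairs ** (1 / 3)))
    dims = [per_axis, per_axis, int(np.ceil(n_pairs / per_axis ** 2))]
    cell = SimulationCell.orthorhombic(*(d * spacing for d in dims))
    elements, base = [], []
    k = 0
    for ix in range(dims[0]):
        for iy in range(dims[1]):
            for iz in range(dims[2]):
                if k >= n_pairs:
                    break
                a, b, sep = pairs[k]
                center = (np.array([ix, iy, iz]) + 0.5) * spacing
                elements += [a, b]
                base += [center - [sep / 2, 0, 0], center + [sep / 2, 0, 0]]
                k += 1
    base = np.array(base)
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    positions = base[None] + rng.normal(
        scale=jitter, size=(n_steps + 1, len(base), 3))
    times = np.arange(n_steps + 1) * dt
    return Trajectory(np.array(elements), times, positions,
                      [cell] * (n_steps + 1), metadata={"counts": dict(
                          (("-".join(k)), v) for k, v in counts.items())})


# ---------------------------------------------------------------------------
# Brownian fixture
# ---------------------------------------------------------------------------

@dataclass
class BrownianSpec:
    """Independent 3D Brownian walkers with known diffusion coefficient."""

    n_atoms: int = 36
    D: float = 2.35e-5          # cm²/s
    duration: float = 4000.0    # fs
    dt: float = 0.242           # fs
    seed: int = 0
    element: str = "Fe"
    box: float = 200.0          # Å, nominal periodic box


def brownian_trajectory(spec: BrownianSpec) -> Trajectory:
    """Gaussian displacements with per-axis step variance 2·D·dt.

    Unwrapped coordinates are stored, so the Einstein MSD estimator can
    recover D exactly in expectation.
    """
    if spec.dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(spec.seed)
    n_steps = int(round(spec.duration / spec.dt))
    d_internal = spec.D * CM2_S_TO_A2_FS            # Å²/fs
    sigma = math.sqrt(2.0 * d_internal * spec.dt)   # Å per axis per step
    start = rng.uniform(0, spec.box, size=(spec.n_atoms, 3))
    steps = rng.normal(scale=sigma, size=(n_steps, spec.n_atoms, 3)) \
        if sigma > 0 else np.zeros((n_steps, spec.n_atoms, 3))
    unwrapped = np.concatenate([start[None],
                                start[None] + np.cumsum(steps, axis=0)])
    times = np.arange(n_steps + 1) * spec.dt
    cell = SimulationCell.orthorhombic(spec.box, spec.box, spec.box)
    return Trajectory([spec.element] * spec.n_atoms, times, unwrapped,
                      [cell] * (n_steps + 1),
                      metadata={"D_true": spec.D, "seed": spec.seed})


# ---------------------------------------------------------------------------
# shock-profile fixture
# ---------------------------------------------------------------------------

def shock_profile_fixture(
    Vs: float,
    final_compression: float,
    rise_time: float = 300.0,
    duration: float = 4000.0,
    dt: float = 2.42,
    rho0: float = 2.386,
    P0: float = 0.0,
    T0: float = 300.0,
    T_final: float = 2100.0,
    width: float | None = None,
) -> pd.DataFrame:
    """Analytic shock-state table emulating the rapid rise near 0.3 ps.

    V/V0 follows a sigmoid from 1 to *final_compression* centred at
    *rise_time*; P and U_p are derived row by row from the jump
    conditions at the instantaneous compression, so every row satisfies
    them identically.  ``width -> 0`` gives a step function.
    """
    if not 0.0 < final_compression < 1.0:
        raise ValueError("final_compression must be in (0, 1)")
    t = np.arange(0.0, duration + dt, dt)
    w = rise_time / 5.0 if width is None else width
    if w <= 0:
        s = (t >= rise_time).astype(float)
    else:
        s = 1.0 / (1.0 + np.exp(-(t - rise_time) / w))
    eta = 1.0 - (1.0 - final_compression) * s
    rows = [hugoniot_jump(rho0, Vs, compression=e, P0=P0) for e in eta]
    return pd.DataFrame({
        "t": t,
        "V_over_V0": eta,
        "P": [r.P for r in rows],
        "U_p": [r.U_p for r in rows],
        "T": T0 + (T_final - T0) * s,
    })


# ---------------------------------------------------------------------------
# Lennard-Jones crystal fixtures for the dynamics engines
# ---------------------------------------------------------------------------

def lj_crystal(
    n_cells: tuple[int, int, int] = (3, 3, 3),
    element: str = "Ar",
    epsilon: float = 0.0104,
    sigma: float = 3.4,
    cutoff: float | None = None,
    lattice_const: float | None = None,
) -> tuple[Frame, Potential]:
    """Face-centered-cubic crystal plus its Lennard-Jones potential.

    If ``lattice_const`` is not given, it is chosen by minimizing the
    lattice energy of the truncated (shifted-force) potential, so the
    crystal starts at mechanical equilibrium (zero stress).  The cutoff
    is capped just below half the smallest box length so the
    minimum-image convention stays valid.
    """
    base_cutoff = 2.5 * sigma if cutoff is None else cutoff
    # valid for every lattice constant visited by the scan (a >= 1.3 sigma)
    cutoff_used = min(base_cutoff, 0.495 * min(n_cells) * 1.3 * sigma)
    pot = PairPotential({(element, element):
                         PairTerm("lj", epsilon, sigma, cutoff_used)})

    def build(a: float) -> Frame:
        basis = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5],
                          [0, 0.5, 0.5]])
        pos, els = [], []
        for ix in range(n_cells[0]):
            for iy in range(n_cells[1]):
                for iz in range(n_cells[2]):
                    for b in basis:
                        pos.append((np.array([ix, iy, iz]) + b) * a)
                        els.append(element)
        cell = SimulationCell.orthorhombic(*(n * a for n in n_cells))
        return Frame(np.array(els), np.array(pos), cell)

    if lattice_const is None:
        from scipy.optimize import minimize_scalar

        def energy(a):
            f = build(a)
            return pot.bind(f.elements).evaluate(f.positions, f.cell).energy

        res = minimize_scalar(energy, bounds=(1.3 * sigma, 1.8 * sigma),
                              method="bounded", options={"xatol": 1e-8})
        lattice_const = float(res.x)
    return build(lattice_const), pot
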