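"""Turn trajectories into chemistry.

Bond definition: two atoms are bonded once they have remained within the
element-pair cutoff distance *continuously* for a prescribed lifetime
(default 2.42 fs = 10 frames at a 0.242 fs timestep), and the bond drops
the moment the distance exceeds the cutoff.  Cutoffs default to the
values determined from the first minima of partial radial distribution
functions of the shocked Fe/N2/H2O system (H-O 1.25, O-Fe 1.50, H-N
2.00, H-Fe 2.50 Å) plus covalent additions needed to close molecular
graphs for speciation (N-N, H-H, N-Fe); every entry is overridable.

Molecules are connected components of the per-frame bond graph;
formation events fire when a tracked atom's component first attains a
target formula (cumulative: later protonation of NH3 to NH4 does not
decrement the count).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .trajectory import Trajectory

logger = logging.getLogger(__name__)

PairKey = tuple[str, str]


def pair_key(a: str, b: str) -> PairKey:
    """Unordered element-pair key (H-O and O-H are the same bond type)."""
    return (a, b) if a <= b else (b, a)


#: cutoffs from the first minima of the shocked-system partial RDFs
RDF_CUTOFFS: dict[PairKey, float] = {
    pair_key("H", "O"): 1.25,
    pair_key("O", "Fe"): 1.50,
    pair_key("H", "N"): 2.00,
    pair_key("H", "Fe"): 2.50,
}

#: covalent additions so the speciation graph can close N-N, H-H, N-Fe
COVALENT_EXTRAS: dict[PairKey, float] = {
    pair_key("N", "N"): 1.8,
    pair_key("H", "H"): 1.0,
    pair_key("N", "Fe"): 2.3,
}


@dataclass(frozen=True)
class BondCriteria:
    """Cutoff table (Å, unordered element pairs) and bond lifetime (fs)."""

    cutoffs: Mapping[PairKey, float] = field(
        default_factory=lambda: {**RDF_CUTOFFS, **COVALENT_EXTRAS})
    lifetime: float = 2.42

    def __post_init__(self) -> None:
        cut = {pair_key(*k): float(v) for k, v in self.cutoffs.items()}
        if any(v <= 0 for v in cut.values()):
            raise ValueError("cutoffs must be positive")
        if self.lifetime <= 0:
            raise ValueError("lifetime must be positive")
        object.__setattr__(self, "cutoffs", cut)

    def frames_required(self, dt: float) -> int:
        """Lifetime expressed as an integer number of frames L."""
        L = round(self.lifetime / dt)
        if L < 1 or abs(self.lifetime / dt - L) > 1e-6 * max(1.0, L):
            raise ValueError(
                f"timestep {dt} fs does not divide lifetime {self.lifetime} fs")
        return int(L)


@dataclass
class PairTypeBonds:
    """Per-frame bond state for one element-pair type.

    Only candidate atom pairs that come within the cutoff at least once
    are kept; ``within`` is the raw cutoff criterion and ``bonded`` the
    lifetime-filtered one.
    """

    pairs: np.ndarray        # (P, 2) atom index pairs
    within: np.ndarray       # (F, P) bool
    bonded: np.ndarray       # (F, P) bool


class BondTimeSeries:
    """Lifetime-filtered bonds for every frame of a trajectory."""

    def __init__(self, elements: np.ndarray, times: np.ndarray,
                 per_type: dict[PairKey, PairTypeBonds], criteria: BondCriteria):
        self.elements = elements
        self.times = times
        self.per_type = per_type
        self.criteria = criteria

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def counts(self, ptype: PairKey | str) -> np.ndarray:
        """Integer bond-count time series for one pair type."""
        key = pair_key(*ptype) if not isinstance(ptype, str) else pair_key(*ptype.split("-"))
        if key not in self.criteria.cutoffs:
            raise KeyError(f"pair type {key} has no cutoff entry")
        ptb = self.per_type.get(key)
        if ptb is None:
            return np.zeros(self.n_frames, dtype=int)
        return ptb.bonded.sum(axis=1).astype(int)

    def unfiltered_counts(self, ptype: PairKey) -> np.ndarray:
        key = pair_key(*ptype)
        ptb = self.per_type.get(key)
        if ptb is None:
            return np.zeros(self.n_frames, dtype=int)
        return ptb.within.sum(axis=1).astype(int)

    def bonds_at(self, frame_index: int) -> np.ndarray:
        """(B, 2) array of bonded atom index pairs at one frame."""
        chunks = [ptb.pairs[ptb.bonded[frame_index]]
                  for ptb in self.per_type.values()]
        chunks = [c for c in chunks if len(c)]
        if not chunks:
            return np.empty((0, 2), dtype=int)
        return np.vstack(chunks)

    def change_frames(self) -> np.ndarray:
        """Frame indices at which any bond appears or disappears."""
        changed = np.zeros(self.n_frames, dtype=bool)
        changed[0] = True
        for ptb in self.per_type.values():
            if ptb.bonded.shape[1]:
                changed[1:] |= np.any(
                    ptb.bonded[1:] != ptb.bonded[:-1], axis=1)
        return np.nonzero(changed)[0]

    def counts_table(self) -> pd.DataFrame:
        data = {"t": self.times}
        for key in self.per_type:
            data["-".join(key)] = self.counts(key)
        return pd.DataFrame(data)


def detect_bonds(trajectory: Trajectory, criteria: BondCriteria | None = None,
                 chunk: int = 512) -> BondTimeSeries:
    """Lifetime-filtered bond detection over a whole trajectory.

    A bond is reported from the first frame at which L consecutive
    within-cutoff frames are completed (L = lifetime/dt) and drops
    immediately when the distance exceeds the cutoff.  Element pairs
    absent from the cutoff table are skipped (logged once).
    """
    criteria = criteria or BondCriteria()
    if len(trajectory) > 1:
        L = criteria.frames_required(trajectory.dt)
    else:
        L = 1 if criteria.lifetime <= 0 else criteria.frames_required(criteria.lifetime)
    elements = trajectory.elements
    n_frames = len(trajectory)
    by_el: dict[str, np.ndarray] = {}
    for el in np.unique(elements):
        by_el[el] = np.nonzero(elements == el)[0]

    present_pairs = {pair_key(a, b) for a in by_el for b in by_el}
    skipped = present_pairs - set(criteria.cutoffs)
    if skipped:
        logger.warning("no cutoff for element pairs %s; skipped",
                       sorted("-".join(p) for p in skipped))

    # orthorhombic fast path: per-frame diagonal cell lengths
    cells_h = np.stack([c.h for c in trajectory.cells])
    ortho = np.allclose(cells_h, cells_h * np.eye(3))
    diag = np.einsum("fii->fi", cells_h)

    per_type: dict[PairKey, PairTypeBonds] = {}
    pos = trajectory.positions
    for key, cutoff in criteria.cutoffs.items():
        a, b = key
        if a not in by_el or b not in by_el:
            continue
        if a == b:
            idx = by_el[a]
            ii, jj = np.triu_indices(len(idx), k=1)
            pairs = np.column_stack([idx[ii], idx[jj]])
        else:
            pairs = np.array(np.meshgrid(by_el[a], by_el[b],
                                         indexing="ij")).reshape(2, -1).T
        if len(pairs) == 0:
            continue
        within = np.empty((n_frames, len(pairs)), dtype=bool)
        for f0 in range(0, n_frames, chunk):
            f1 = min(f0 + chunk, n_frames)
            d = pos[f0:f1, pairs[:, 1]] - pos[f0:f1, pairs[:, 0]]
            if ortho:
                box = diag[f0:f1, None, :]
                d -= box * np.round(d / box)
            else:
                for f in range(f0, f1):
                    d[f - f0] = trajectory.cells[f].minimum_image(d[f - f0])
            within[f0:f1] = np.einsum("fpk,fpk->fp", d, d) <= cutoff * cutoff
        keep = within.any(axis=0)
        if not keep.any():
            continue
        within = within[:, keep]
        bonded = _lifetime_filter(within, L)
        per_type[key] = PairTypeBonds(pairs[keep], within, bonded)

    return BondTimeSeries(elements, trajectory.times.copy(), per_type, criteria)


def _lifetime_filter(within: np.ndarray, L: int) -> np.ndarray:
    """bonded[t] = all(within[t-L+1 .. t]) via a running window sum."""
    if L == 1:
        return within.copy()
    c = np.cumsum(within, axis=0, dtype=np.int32)
    bonded = np.zeros_like(within)
    bonded[L - 1] = c[L - 1] == L
    bonded[L:] = (c[L:] - c[:-L]) == L
    return bonded


def count_bonds(bond_series: BondTimeSeries, ptype: PairKey | str) -> np.ndarray:
    """Time series of lifetime-filtered bond counts for one pair type."""
    return bond_series.counts(ptype)


# ---------------------------------------------------------------------------
# speciation
# ---------------------------------------------------------------------------

#: named species recognized by the census, as element multisets
NAMED_SPECIES: dict[str, dict[str, int]] = {
    "NH3": {"N": 1, "H": 3},
    "NH4": {"N": 1, "H": 4},
    "N2H4": {"N": 2, "H": 4},
    "N2H5": {"N": 2, "H": 5},
    "H3O": {"O": 1, "H": 3},
    "OH": {"O": 1, "H": 1},
    "H2O": {"O": 1, "H": 2},
    "N2": {"N": 2},
}

_DISPLAY_ORDER = ["N", "H", "O", "Fe"]


def formula_string(formula: Mapping[str, int]) -> str:
    """Readable formula label (N, H, O, Fe first, then alphabetical)."""
    keys = [k for k in _DISPLAY_ORDER if k in formula]
    keys += sorted(k for k in formula if k not in _DISPLAY_ORDER)
    return "".join(f"{k}{formula[k] if formula[k] > 1 else ''}" for k in keys)


@dataclass
class SpeciesCensus:
    """Molecular inventory of one frame."""

    frame_index: int
    time: float
    components: list[tuple[frozenset, Counter]]   # (atom ids, formula)

    def formulas(self) -> Counter:
        """Multiset of formula strings."""
        return Counter(formula_string(f) for _, f in self.components)

    def species_count(self, name: str) -> int:
        target = NAMED_SPECIES[name]
        return sum(1 for _, f in self.components if dict(f) == target)

    def total_composition(self) -> Counter:
        tot: Counter = Counter()
        for _, f in self.components:
            tot += f
        return tot


def species_census(bond_series: BondTimeSeries, frame_index: int) -> SpeciesCensus:
    """Connected components of the bond graph at one frame, with formulas.

    Isolated atoms count as single-atom components, so the census always
    conserves the element totals.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(bond_series.elements)))
    g.add_edges_from(map(tuple, bond_series.bonds_at(frame_index)))
    comps = []
    for comp in nx.connected_components(g):
        formula = Counter(bond_series.elements[list(comp)].tolist())
        comps.append((frozenset(comp), formula))
    return SpeciesCensus(frame_index, float(bond_series.times[frame_index]), comps)


@dataclass
class FormationEvent:
    """First attainment of a target formula by a tracked atom."""

    formula: str
    time: float            # fs
    frame_index: int
    atoms: frozenset       # participating atom ids
    tracked_atom: int


def cumulative_formation_events(
    bond_series: BondTimeSeries,
    formula: Mapping[str, int] | str = "NH3",
    tracked_element: str | None = None,
) -> tuple[list[FormationEvent], np.ndarray]:
    """Cumulative first-formation events of a target species.

    An event fires when a tracked atom (by default the rarest element of
    the formula, N for NH3) first sits in a connected component whose
    formula equals the target exactly.  The returned cumulative count
    series is monotone non-decreasing: later transformations (e.g.
    protonation of NH3 to NH4+) never decrement it.
    """
    if isinstance(formula, str):
        target = dict(NAMED_SPECIES[formula])
        name = formula
    else:
        target = dict(formula)
        name = formula_string(Counter(target))
    if tracked_element is None:
        tracked_element = min(target, key=lambda e: (target[e], e))
    tracked = np.nonzero(bond_series.elements == tracked_element)[0]
    elements = bond_series.elements
    n_frames = bond_series.n_frames
    events: list[FormationEvent] = []
    formed: set[int] = set()

    for f in bond_series.change_frames():
        remaining = [a for a in tracked if a not in formed]
        if not remaining:
            break
        adj: dict[int, list[int]] = {}
        for i, j in bond_series.bonds_at(f):
            adj.setdefault(int(i), []).append(int(j))
            adj.setdefault(int(j), []).append(int(i))
        seen_this_frame: set[int] = set()
        for atom in remaining:
            if atom in seen_this_frame:
                continue
            comp = _component_of(atom, adj, limit=sum(target.values()) + 1)
            if comp is None:
                continue
            seen_this_frame |= comp
            if dict(Counter(elements[list(comp)].tolist())) == target:
                events.append(FormationEvent(
                    formula=name, time=float(bond_series.times[f]),
                    frame_index=int(f), atoms=frozenset(comp),
                    tracked_atom=int(atom)))
                formed.add(atom)

    cumulative = np.zeros(n_frames, dtype=int)
    for ev in events:
        cumulative[ev.frame_index:] += 1
    return events, cumulative


def _component_of(atom: int, adj: dict[int, list[int]], limit: int) -> set[int] | None:
    """BFS component containing *atom*; None if it exceeds *limit* atoms."""
    comp = {atom}
    queue = [atom]
    while queue:
        a = queue.pop()
        for b in adj.get(a, ()):
            if b not in comp:
                comp.add(b)
                if len(comp) > limit:
                    return None
                queue.append(b)
    return comp


# ---------------------------------------------------------------------------
# partial RDF and cutoff determination
# ---------------------------------------------------------------------------

def partial_rdf(trajectory: Trajectory, pair: PairKey, bin_width: float = 0.05,
                r_max: float = 6.0) -> pd.DataFrame:
    """Partial radial distribution function g_ab(r).

    Normalized so that g -> 1 at large r for a homogeneous system.
    Returns a table with columns ``r`` (bin centers) and ``g``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    a, b = pair
    ia = np.nonzero(trajectory.elements == a)[0]
    ib = np.nonzero(trajectory.elements == b)[0]
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError(f"no atoms of requested elements {a}-{b}")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    n_pairs_norm = 0.0
    for k in range(len(trajectory)):
        cell = trajectory.cells[k]
        pos = trajectory.positions[k]
        if a == b:
            ii, jj = np.triu_indices(len(ia), k=1)
            d = cell.minimum_image(pos[ia[jj]] - pos[ia[ii]])
            mult = 2.0
            n_b = len(ia) - 1
        else:
            d = cell.minimum_image(
                pos[ib][None, :, :] - pos[ia][:, None, :]).reshape(-1, 3)
            mult = 1.0
            n_b = len(ib)
        r = np.linalg.norm(d, axis=1)
        hist += mult * np.histogram(r, bins=edges)[0]
        n_pairs_norm += len(ia) * n_b / cell.volume
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = hist / (shell * n_pairs_norm)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"r": centers, "g": g})


def first_minimum(rdf: pd.DataFrame, smooth_bins: int = 5) -> float:
    """Location of the first minimum of g(r) after the first peak.

    g(r) is smoothed with a ``smooth_bins`` moving average before the
    first peak and the following valley are located.
    """
    g = rdf["g"].to_numpy(dtype=float)
    r = rdf["r"].to_numpy(dtype=float)
    kern = np.ones(smooth_bins) / smooth_bins
    gs = np.convolve(g, kern, mode="same")
    # first local maximum with non-trivial height
    peaks = np.nonzero((gs[1:-1] > gs[:-2]) & (gs[1:-1] >= gs[2:])
                       & (gs[1:-1] > 0.1 * gs.max()))[0] + 1
    if len(peaks) == 0:
        raise ValueError("no peak found in g(r)")
    p1 = peaks[0]
    later = peaks[peaks > p1]
    p2 = later[0] if len(later) else len(gs) - 1
    valley = p1 + int(np.argmin(gs[p1:p2 + 1]))
    return float(r[valley])


# ---------------------------------------------------------------------------
# Mulliken-charge bookkeeping
# ---------------------------------------------------------------------------

#: valence electrons of the isolated neutral atom for the projector set
#: used by the population analysis (2s2p for N and O, 1s for H, 3d4s for Fe)
DEFAULT_VALENCE: dict[str, float] = {"N": 5.0, "O": 6.0, "H": 1.0, "Fe": 8.0}


def mulliken_charge(
    elements: Sequence[str],
    gross_population: np.ndarray,
    valence: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Mulliken charges Q_i(t) = Z0_i - Z_i(t).

    ``gross_population`` is an (n_frames, n_atoms) array of per-atom
    gross populations Z_i(t) (input data from a population analysis; not
    computed here).  Q < 0 marks a reduced (electron-rich) atom.
    """
    valence = DEFAULT_VALENCE if valence is None else valence
    elements = list(elements)
    missing = sorted({e for e in elements if e not in valence})
    if missing:
        raise KeyError(f"no valence count for element(s) {missing}")
    z0 = np.array([valence[e] for e in elements], dtype=float)
    z = np.asarray(gross_population, dtype=float)
    return z0 - z


def read_population_table(path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read a long-format per-atom gross-population table.

    Expected delimited columns: ``t, atom, element, Z``.  Returns
    (elements, times, Z array of shape (n_times, n_atoms)).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    need = {"t", "atom", "element", "Z"}
    if not need.issubset(df.columns):
        raise ValueError(f"population table must have columns {sorted(need)}")
    wide = df.pivot(index="t", columns="atom", values="Z").sort_index()
    el = (df.drop_duplicates("atom").sort_values("atom")["element"].tolist())
    return el, wide.index.to_numpy(float), wide.to_numpy(float)
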