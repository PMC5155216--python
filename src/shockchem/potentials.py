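"""Classical interatomic potentials for the dynamics engine.

These stand in for the potential-energy surface driving the shock
dynamics: pairwise Lennard-Jones or Morse terms keyed by element pair
(with shifted-force truncation so forces are continuous at the cutoff
and the dynamics conserve energy exactly for the truncated model), plus
optional harmonic intramolecular bonds for scripted fixtures.

All energies are eV, lengths Å; forces eV/Å.  ``evaluate`` also returns
the diagonal of the pairwise virial tensor, W_aa = Σ_pairs f_a,ij·r_a,ij,
needed by the shock engine's axial stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .trajectory import SimulationCell

PairKey = tuple[str, str]


def _key(a: str, b: str) -> PairKey:
    return (a, b) if a <= b else (b, a)


@dataclass
class EvalResult:
    energy: float
    forces: np.ndarray          # (N, 3) eV/Å
    virial_diag: np.ndarray     # (3,) eV, Σ f_a*r_a over pairs


class Potential:
    """Base class; concrete potentials implement ``bind``."""

    def bind(self, elements: Sequence[str]) -> "BoundPotential":
        raise NotImplementedError


class BoundPotential:
    """Potential specialized to a fixed atom list."""

    def evaluate(self, positions: np.ndarray, cell: SimulationCell) -> EvalResult:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# pairwise potentials
# ---------------------------------------------------------------------------

@dataclass
class PairTerm:
    form: str                   # "lj" or "morse"
    epsilon: float              # well depth, eV
    length: float               # sigma (lj) or r0 (morse), Å
    cutoff: float               # Å
    alpha: float = 1.0          # morse width, 1/Å (unused for lj)


class PairPotential(Potential):
    """Pairwise potential with per-element-pair terms.

    Lennard-Jones terms use shifted-force truncation; Morse terms use
    energy-shift truncation (their forces at typical cutoffs are already
    negligible).
    """

    def __init__(self, terms: Mapping[PairKey, PairTerm]):
        self.terms = { _key(*k): v for k, v in terms.items() }

    @classmethod
    def lennard_jones(cls, element: str, epsilon: float, sigma: float,
                      cutoff: float | None = None) -> "PairPotential":
        cutoff = 2.5 * sigma if cutoff is None else cutoff
        return cls({(element, element): PairTerm("lj", epsilon, sigma, cutoff)})

    def bind(self, elements: Sequence[str]) -> "BoundPairPotential":
        return BoundPairPotential(self, elements)


class BoundPairPotential(BoundPotential):
    def __init__(self, pot: PairPotential, elements: Sequence[str]):
        elements = list(elements)
        n = len(elements)
        ii, jj = np.triu_indices(n, k=1)
        keep, eps, length, cut, alpha, form = [], [], [], [], [], []
        for k in range(len(ii)):
            term = pot.terms.get(_key(elements[ii[k]], elements[jj[k]]))
            if term is None:
                continue
            keep.append(k)
            eps.append(term.epsilon)
            length.append(term.length)
            cut.append(term.cutoff)
            alpha.append(term.alpha)
            form.append(term.form)
        self.i = ii[keep]
        self.j = jj[keep]
        self.eps = np.array(eps)
        self.length = np.array(length)
        self.cut = np.array(cut)
        self.alpha = np.array(alpha)
        self.is_lj = np.array([f == "lj" for f in form])
        self.n = n

    def evaluate(self, positions: np.ndarray, cell: SimulationCell) -> EvalResult:
        forces = np.zeros((self.n, 3))
        virial = np.zeros(3)
        if len(self.i) == 0:
            return EvalResult(0.0, forces, virial)
        d = cell.minimum_image(positions[self.j] - positions[self.i])
        r = np.linalg.norm(d, axis=1)
        if np.any(r < 1e-6):
            raise FloatingPointError("atom overlap: pair distance below 1e-6 Å")
        within = r < self.cut
        energy = 0.0
        # dU/dr for each pair (zero beyond cutoff)
        dudr = np.zeros_like(r)
        e_pair = np.zeros_like(r)

        lj = within & self.is_lj
        if np.any(lj):
            sr6 = (self.length[lj] / r[lj]) ** 6
            rc = self.cut[lj]
            src6 = (self.length[lj] / rc) ** 6
            u = 4 * self.eps[lj] * (sr6 ** 2 - sr6)
            up = -24 * self.eps[lj] * (2 * sr6 ** 2 - sr6) / r[lj]
            uc = 4 * self.eps[lj] * (src6 ** 2 - src6)
            upc = -24 * self.eps[lj] * (2 * src6 ** 2 - src6) / rc
            # shifted-force: U(r) - U(rc) - (r - rc) U'(rc)
            e_pair[lj] = u - uc - (r[lj] - rc) * upc
            dudr[lj] = up - upc

        mo = within & ~self.is_lj
        if np.any(mo):
            ex = np.exp(-self.alpha[mo] * (r[mo] - self.length[mo]))
            exc = np.exp(-self.alpha[mo] * (self.cut[mo] - self.length[mo]))
            e_pair[mo] = self.eps[mo] * ((1 - ex) ** 2 - (1 - exc) ** 2)
            dudr[mo] = 2 * self.eps[mo] * self.alpha[mo] * (1 - ex) * ex

        energy = float(e_pair.sum())
        # force on atom j along +d is -dU/dr * d/r
        fvec = (-dudr / r)[:, None] * d
        np.add.at(forces, self.j, fvec)
        np.add.at(forces, self.i, -fvec)
        virial += (fvec * d).sum(axis=0)
        return EvalResult(energy, forces, virial)


class HarmonicBondPotential(Potential):
    """Explicit harmonic bonds: U = ½ k (r - r0)² per bond (minimum image)."""

    def __init__(self, bonds: Sequence[tuple[int, int, float, float]]):
        # (i, j, k eV/Å², r0 Å)
        self.bonds = list(bonds)

    def bind(self, elements: Sequence[str]) -> "BoundHarmonic":
        return BoundHarmonic(self, len(elements))


class BoundHarmonic(BoundPotential):
    def __init__(self, pot: HarmonicBondPotential, n: int):
        arr = np.array(pot.bonds, dtype=float).reshape(-1, 4)
        self.i = arr[:, 0].astype(int)
        self.j = arr[:, 1].astype(int)
        self.k = arr[:, 2]
        self.r0 = arr[:, 3]
        self.n = n

    def evaluate(self, positions: np.ndarray, cell: SimulationCell) -> EvalResult:
        forces = np.zeros((self.n, 3))
        virial = np.zeros(3)
        if len(self.i) == 0:
            return EvalResult(0.0, forces, virial)
        d = cell.minimum_image(positions[self.j] - positions[self.i])
        r = np.linalg.norm(d, axis=1)
        energy = float((0.5 * self.k * (r - self.r0) ** 2).sum())
        dudr = self.k * (r - self.r0)
        fvec = (-dudr / r)[:, None] * d
        np.add.at(forces, self.j, fvec)
        np.add.at(forces, self.i, -fvec)
        virial += (fvec * d).sum(axis=0)
        return EvalResult(energy, forces, virial)


class CompositePotential(Potential):
    def __init__(self, parts: Sequence[Potential]):
        self.parts = list(parts)

    def bind(self, elements: Sequence[str]) -> "BoundComposite":
        return BoundComposite([p.bind(elements) for p in self.parts])


class BoundComposite(BoundPotential):
    def __init__(self, parts):
        self.parts = parts

    def evaluate(self, positions, cell) -> EvalResult:
        res = [p.evaluate(positions, cell) for p in self.parts]
        return EvalResult(
            sum(r.energy for r in res),
            sum(r.forces for r in res),
            sum(r.virial_diag for r in res),
        )


class ZeroPotential(Potential):
    """Free particles; useful for fixed-point and plumbing tests."""

    def bind(self, elements: Sequence[str]) -> BoundPotential:
        n = len(elements)

        class _Zero(BoundPotential):
            def evaluate(self, positions, cell):
                return EvalResult(0.0, np.zeros((n, 3)), np.zeros(3))

        return _Zero()


def numerical_forces(bound: BoundPotential, positions: np.ndarray,
                     cell: SimulationCell, h: float = 1e-5) -> np.ndarray:
    """Central-finite-difference forces, for consistency checks."""
    f = np.zeros_like(positions)
    for a in range(positions.shape[0]):
        for ax in range(3):
            p = positions.copy()
            p[a, ax] += h
            ep = bound.evaluate(p, cell).energy
            p[a, ax] -= 2 * h
            em = bound.evaluate(p, cell).energy
            f[a, ax] = -(ep - em) / (2 * h)
    return f
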