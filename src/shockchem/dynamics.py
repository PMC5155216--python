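"""Molecular-dynamics engines: NVE/NVT, MSST shock propagation, and
distance-constrained dynamics recording the constraint's Lagrange
multiplier.

The shock engine implements the multi-scale shock technique (MSST): the
computational cell's volume is a dynamical degree of freedom driven so
that the axial stress follows the Rayleigh line
``P = P0 + rho0*Vs^2*(1 - V/V0)`` and the system energy the Hugoniot
relation of a steady shock travelling at speed ``Vs``.  The cell moves
under ``(Q/M) V'' = P_xx - P0 - rho0*Vs^2*(1 - V/V0)`` — the
Euler-Lagrange stationarity condition of the extended Lagrangian whose
fictitious cell-mass parameter ``Q`` carries units mass²·length⁻⁴ and
``M`` is the total mass.  Uniaxial strain: only the x cell length
evolves; atom x coordinates are propagated in scaled form so the
material compresses with the cell.

Internally the integrators work in amu/Å/fs mechanical units; the
potential's eV energies and eV/Å forces are converted on evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .potentials import BoundPotential, Potential
from .trajectory import Frame, SimulationCell, Trajectory
from .units import (
    A_FS_TO_KMS,
    EV_TO_INTERNAL,
    GPA_PER_INTERNAL_P,
    INTERNAL_TO_EV,
    K_B,
    KMS_TO_A_FS,
)


class IntegrationError(RuntimeError):
    """Numerical failure during time integration (with step index)."""


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def maxwell_boltzmann_velocities(masses: np.ndarray, T: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Seeded Maxwell-Boltzmann draw (Å/fs), COM removed, rescaled so the
    instantaneous kinetic temperature equals *T* exactly (ndof = 3N-3)."""
    n = len(masses)
    if T <= 0:
        return np.zeros((n, 3))
    sigma = np.sqrt(K_B * T * EV_TO_INTERNAL / masses)
    v = rng.normal(size=(n, 3)) * sigma[:, None]
    v -= (masses[:, None] * v).sum(axis=0) / masses.sum()
    ndof = max(3 * n - 3, 1)
    ke = 0.5 * (masses[:, None] * v ** 2).sum() * INTERNAL_TO_EV
    target = 0.5 * ndof * K_B * T
    if ke > 0:
        v *= np.sqrt(target / ke)
    return v


def kinetic_temperature(masses: np.ndarray, velocities: np.ndarray,
                        ndof: int | None = None) -> float:
    """Instantaneous kinetic temperature in K."""
    n = len(masses)
    if ndof is None:
        ndof = max(3 * n - 3, 1)
    ke = 0.5 * (masses[:, None] * velocities ** 2).sum() * INTERNAL_TO_EV
    return 2.0 * ke / (ndof * K_B)


def _forces_internal(bound: BoundPotential, positions: np.ndarray,
                     cell: SimulationCell, step: int):
    try:
        res = bound.evaluate(positions, cell)
    except FloatingPointError as exc:
        raise IntegrationError(f"step {step}: {exc}") from exc
    f = res.forces * EV_TO_INTERNAL
    if not np.all(np.isfinite(f)):
        raise IntegrationError(f"step {step}: non-finite forces (atom overlap?)")
    return res.energy, f, res.virial_diag * EV_TO_INTERNAL


# ---------------------------------------------------------------------------
# canonical / microcanonical dynamics
# ---------------------------------------------------------------------------

def run_nvt(
    frame: Frame,
    potential: Potential,
    T: float | None,
    dt: float,
    n_steps: int,
    seed: int | None = 0,
    tau_factor: float = 50.0,
    stride: int = 1,
) -> Trajectory:
    """Velocity-Verlet dynamics with a single Nosé-Hoover thermostat.

    ``T=None`` (or thermostat coupling disabled) gives plain NVE.  The
    thermostat mass is set from the coupling period ``tau_factor*dt``.
    Returns a trajectory of ``n_steps/stride + 1`` frames carrying
    velocities; per-frame kinetic/potential energies are stored in
    ``metadata["energy"]`` (columns t, E_kin, E_pot, T).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if T is not None and T < 0:
        raise ValueError("temperature must be non-negative")
    masses = frame.masses()
    n = frame.n_atoms
    ndof = max(3 * n - 3, 1)
    cell = frame.cell
    x = frame.positions.copy()
    if frame.velocities is not None:
        v = frame.velocities.copy()
    else:
        rng = np.random.default_rng(seed)
        v = maxwell_boltzmann_velocities(masses, T or 0.0, rng)
    bound = potential.bind(frame.elements)

    thermostat = T is not None and T > 0
    xi = 0.0
    q_t = ndof * K_B * T * EV_TO_INTERNAL * (tau_factor * dt) ** 2 if thermostat else 1.0
    gkt = ndof * K_B * T * EV_TO_INTERNAL if thermostat else 0.0

    def ke_internal():
        return 0.5 * (masses[:, None] * v ** 2).sum()

    def thermo_half():
        nonlocal xi, v
        if not thermostat:
            return
        xi += 0.25 * dt * (2 * ke_internal() - gkt) / q_t
        v *= np.exp(-xi * 0.5 * dt)
        xi += 0.25 * dt * (2 * ke_internal() - gkt) / q_t

    epot, f, _ = _forces_internal(bound, x, cell, 0)
    frames = []
    energies = []

    def record(step):
        ke = ke_internal() * INTERNAL_TO_EV
        energies.append((step * dt, ke, epot,
                         2 * ke / (ndof * K_B)))
        frames.append(Frame(frame.elements, x.copy(), cell, time=step * dt,
                            velocities=v.copy(), unwrapped=x.copy()))

    record(0)
    for step in range(1, n_steps + 1):
        thermo_half()
        v += 0.5 * dt * f / masses[:, None]
        x += dt * v
        epot, f, _ = _forces_internal(bound, x, cell, step)
        v += 0.5 * dt * f / masses[:, None]
        thermo_half()
        if step % stride == 0 or step == n_steps:
            record(step)

    traj = Trajectory.from_frames(frames, metadata={
        "energy": pd.DataFrame(energies, columns=["t", "E_kin", "E_pot", "T"]),
        "seed": seed, "dt": dt,
    })
    return traj


def run_nve(frame: Frame, potential: Potential, dt: float, n_steps: int,
            stride: int = 1) -> Trajectory:
    """Microcanonical dynamics (thermostat off, cell frozen)."""
    if frame.velocities is None:
        raise ValueError("NVE requires initial velocities on the frame")
    return run_nvt(frame, potential, T=None, dt=dt, n_steps=n_steps,
                   stride=stride)


# ---------------------------------------------------------------------------
# MSST
# ---------------------------------------------------------------------------

@dataclass
class MSSTState:
    """Instantaneous state of the shock-driven cell."""

    t: float                 # fs
    V: float                 # Å³
    compression: float       # V/V0
    P_xx: float              # GPa, axial virial stress
    T: float                 # K
    U_p: float               # km/s, Vs*(1 - V/V0) mass jump diagnostic
    V_dot: float             # Å³/fs
    E_conserved: float       # eV, extended conserved energy


def msst_states_to_frame(states: list[MSSTState]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.t, s.compression, s.P_xx, s.U_p, s.T, s.V, s.V_dot, s.E_conserved)
         for s in states],
        columns=["t", "V_over_V0", "P", "U_p", "T", "V", "V_dot", "E_cons"])


def default_cell_mass(masses: np.ndarray, rho0: float, vs: float, V0: float,
                      dt: float, period_steps: float = 100.0) -> float:
    """Q (amu²·Å⁻⁴) giving a cell-oscillation period of ~``period_steps*dt``
    on the linearized Rayleigh restoring force."""
    M = masses.sum()
    k_eff = rho0 * (vs * KMS_TO_A_FS) ** 2 / V0     # internal pressure / Å³
    return M * k_eff * (period_steps * dt / (2 * np.pi)) ** 2


def run_msst(
    frame: Frame,
    potential: Potential,
    V_s: float,
    Q: float | None = None,
    dt: float = 0.242,
    n_steps: int = 1000,
    P0: float | None = None,
    T0: float = 300.0,
    seed: int | None = 0,
    stride: int = 10,
    initial_vdot: float | None = None,
    cell_damping: float = 0.0,
    V0_ref: float | None = None,
    n_vv_iter: int = 5,
) -> tuple[Trajectory, list[MSSTState]]:
    """Propagate a steady shock with the multi-scale shock technique.

    Parameters
    ----------
    V_s : shock speed, km/s (shock along x; y, z cell lengths fixed).
    Q : fictitious cell mass, amu²·Å⁻⁴; default sets the linearized cell
        oscillation period to ~100 timesteps.
    P0, T0 : unshocked pressure (GPa) and temperature (K).  ``P0=None``
        measures the unshocked pressure from the initial configuration
        (its axial virial stress including the kinetic term), so the
        starting state sits exactly on the Rayleigh line's foot; pass an
        explicit value to override.
    initial_vdot : initial volume rate, Å³/fs; a small negative seed
        (default ``-1e-4*V0``) nudges the cell off the unshocked fixed
        point so compression can nucleate.
    cell_damping : artificial viscosity (1/fs) acting on the cell DOF
        only.  A perfectly elastic crystal cannot thermalize the cell
        oscillation, so without damping the cell rings through V0 and
        runs away on the rarefaction branch; a damped run relaxes onto
        the compressed Rayleigh-line state (which is a stable fixed
        point) and can then be continued undamped.  The damping force
        vanishes at stationarity, so it does not bias the Rayleigh-line
        balance.
    V0_ref : unshocked reference volume, Å³ (default: the initial cell
        volume).  Set it when continuing a run whose cell is already
        compressed.

    Returns the trajectory and the per-stride :class:`MSSTState` series.
    The reported ``U_p = Vs*(1 - V/V0)`` is the mass-conservation jump
    diagnostic and holds identically by construction.
    """
    h = frame.cell.h
    if not np.allclose(h, np.diag(np.diag(h))):
        raise ValueError("MSST requires an orthorhombic cell (shock along x)")
    if Q is not None and Q <= 0:
        raise ValueError("Q must be positive")
    masses = frame.masses()
    M = masses.sum()
    n = frame.n_atoms
    V0 = frame.cell.volume if V0_ref is None else float(V0_ref)
    ly, lz = h[1, 1], h[2, 2]
    area = ly * lz
    rho0 = M / V0
    vs = V_s * KMS_TO_A_FS
    if Q is None:
        Q = default_cell_mass(masses, rho0, V_s, V0, dt)
    # linearized period; warn if the cell DOF is too fast for the timestep
    period = 2 * np.pi * np.sqrt(Q / (M * rho0 * vs ** 2 / V0))
    if period < 10 * dt:
        warnings.warn("Q is small: cell oscillation period below 10 timesteps; "
                      "expect instability", stacklevel=2)

    V = frame.cell.volume
    vdot = -1e-4 * V0 if initial_vdot is None else float(initial_vdot)
    lx = V / area
    sx = frame.positions[:, 0] / lx
    yz = frame.positions[:, 1:3].copy()
    if frame.velocities is not None:
        vel = frame.velocities.copy()
    else:
        rng = np.random.default_rng(seed)
        vel = maxwell_boltzmann_velocities(masses, T0, rng)
    vsx = vel[:, 0] / lx
    vyz = vel[:, 1:3].copy()

    bound = potential.bind(frame.elements)

    def cart_positions(lx_):
        return np.column_stack([sx * lx_, yz])

    def cell_of(lx_):
        return SimulationCell(np.diag([lx_, ly, lz]))

    def u_cell(V_):
        # potential of the cell DOF: -dU/dV = -(P0 + rho0 vs^2 (1 - V/V0))
        return p0 * (V_ - V0) - rho0 * vs ** 2 / (2 * V0) * (V0 - V_) ** 2

    def accelerations(f_int, wxx, lx_, ldotx, V_, vdot_, vsx_, vyz_):
        vx = lx_ * vsx_
        a_sx = f_int[:, 0] / (masses * lx_) - 2.0 * (ldotx / lx_) * vsx_
        a_yz = f_int[:, 1:3] / masses[:, None]
        p_xx = ((masses * vx ** 2).sum() + wxx) / V_
        a_v = (M / Q) * (p_xx - p0 - rho0 * vs ** 2 * (1 - V_ / V0)) \
            - cell_damping * vdot_
        return a_sx, a_yz, a_v, p_xx

    epot, f_int, w_int = _forces_internal(bound, cart_positions(lx), cell_of(lx), 0)
    if P0 is None:
        vx0 = lx * vsx
        p0 = ((masses * vx0 ** 2).sum() + w_int[0]) / V
    else:
        p0 = P0 / GPA_PER_INTERNAL_P

    states: list[MSSTState] = []
    frames: list[Frame] = []

    def record(step):
        vx = lx * vsx
        vel_full = np.column_stack([vx, vyz])
        ke = 0.5 * (masses[:, None] * vel_full ** 2).sum()
        e_cons = (ke + (Q / (2 * M)) * vdot ** 2 + u_cell(V)) * INTERNAL_TO_EV + epot
        p_xx = ((masses * vx ** 2).sum() + w_int[0]) / V
        states.append(MSSTState(
            t=step * dt, V=V, compression=V / V0,
            P_xx=p_xx * GPA_PER_INTERNAL_P,
            T=2 * ke * INTERNAL_TO_EV / (3 * n * K_B),
            U_p=V_s * (1 - V / V0), V_dot=vdot,
            E_conserved=e_cons))
        frames.append(Frame(frame.elements, cart_positions(lx), cell_of(lx),
                            time=step * dt, velocities=vel_full))

    record(0)
    for step in range(1, n_steps + 1):
        ldotx = vdot / area
        a_sx, a_yz, a_v, _ = accelerations(f_int, w_int[0], lx, ldotx, V,
                                           vdot, vsx, vyz)
        vsx_h = vsx + 0.5 * dt * a_sx
        vyz_h = vyz + 0.5 * dt * a_yz
        vdot_h = vdot + 0.5 * dt * a_v
        sx = (sx + dt * vsx_h) % 1.0
        yz = yz + dt * vyz_h
        V = V + dt * vdot_h
        if V < 0.05 * V0:
            raise IntegrationError(
                f"step {step}: cell collapse (V/V0 = {V / V0:.3g}); "
                "increase Q or reduce Vs")
        if V > 1.5 * V0:
            raise IntegrationError(
                f"step {step}: rarefaction runaway (V/V0 = {V / V0:.3g}); "
                "Vs is likely below the material sound speed")
        lx = V / area
        epot, f_int, w_int = _forces_internal(bound, cart_positions(lx),
                                              cell_of(lx), step)
        # velocity-dependent accelerations: fixed-point iteration
        vsx, vyz, vdot = vsx_h, vyz_h, vdot_h
        for _ in range(n_vv_iter):
            ldotx = vdot / area
            a_sx, a_yz, a_v, _ = accelerations(f_int, w_int[0], lx, ldotx, V,
                                               vdot, vsx, vyz)
            vsx = vsx_h + 0.5 * dt * a_sx
            vyz = vyz_h + 0.5 * dt * a_yz
            vdot = vdot_h + 0.5 * dt * a_v
        if step % stride == 0 or step == n_steps:
            record(step)

    traj = Trajectory.from_frames(frames, metadata={
        "V_s": V_s, "Q": Q, "dt": dt, "seed": seed,
        "P0": p0 * GPA_PER_INTERNAL_P})
    return traj, states


def rayleigh_pressure(rho0_internal: float, vs_kms: float, compression: float,
                      P0_gpa: float = 0.0) -> float:
    """Rayleigh-line pressure in GPa at V/V0 = *compression*.

    ``rho0_internal`` is in amu/Å³.
    """
    vs = vs_kms * KMS_TO_A_FS
    p = rho0_internal * vs ** 2 * (1 - compression)
    return P0_gpa + p * GPA_PER_INTERNAL_P


# ---------------------------------------------------------------------------
# constrained dynamics
# ---------------------------------------------------------------------------

@dataclass
class ConstraintResult:
    """Record of one constrained window at fixed pair distance."""

    pair: tuple[int, int]
    r_target: float              # Å
    mean_lambda: float           # eV/Å, equilibration discarded
    lambda_series: np.ndarray    # eV/Å per step
    times: np.ndarray            # fs
    max_residual: float          # Å, worst |r - r_target| seen

    def stderr(self, n_blocks: int = 10) -> float:
        """Block-averaged standard error of the mean multiplier."""
        lam = self.lambda_series[len(self.lambda_series) // 5:]
        blocks = np.array_split(lam, n_blocks)
        bm = np.array([b.mean() for b in blocks])
        return float(bm.std(ddof=1) / np.sqrt(len(bm)))


def constrained_window(
    frame: Frame,
    potential: Potential,
    pair: tuple[int, int],
    r_target: float,
    T: float,
    duration: float,
    dt: float = 0.242,
    seed: int | None = 0,
    equil_frac: float = 0.2,
    tol: float = 1e-10,
    max_iter: int = 500,
    tau_factor: float = 50.0,
    thermostat: str = "nose-hoover",
    friction: float = 0.05,
) -> ConstraintResult:
    """Hold ``|r_i - r_j| = r_target`` with RATTLE and record the
    constraint's Lagrange multiplier each step.

    Sign convention: λ > 0 when the unconstrained potential force would
    lengthen the bond, i.e. the constraint resists expansion.  With this
    convention the free-energy profile ``ΔF(r) = ∫_r^{r0} ⟨λ⟩ dr'`` is
    positive uphill, and a harmonic bond of stiffness k0 constrained at
    ``r0 - δ`` gives ``⟨λ⟩ = k0·δ`` in the low-temperature limit.

    ``⟨λ⟩`` averages the per-step multiplier after discarding the first
    ``equil_frac`` of the window.

    ``thermostat`` selects Nosé-Hoover (deterministic, default) or
    Langevin (``friction`` in 1/fs; stochastic but mixing, so window
    averages obey clean 1/sqrt(duration) statistics even for small or
    near-integrable systems).
    """
    if thermostat not in ("nose-hoover", "langevin"):
        raise ValueError("thermostat must be 'nose-hoover' or 'langevin'")
    i, j = pair
    if i == j:
        raise ValueError("constraint requires two distinct atoms")
    masses = frame.masses()
    mi, mj = masses[i], masses[j]
    mu = mi * mj / (mi + mj)
    cell = frame.cell
    n = frame.n_atoms
    x = frame.positions.copy()

    d = cell.minimum_image(x[j] - x[i])
    r_now = np.linalg.norm(d)
    if abs(r_now - r_target) > 0.5:
        raise ValueError(
            f"initial pair distance {r_now:.3f} Å more than 0.5 Å from "
            f"target {r_target:.3f} Å")
    # project initial geometry exactly onto the constraint
    corr = (r_target / r_now - 1.0) * d
    x[i] -= corr * (mj / (mi + mj))
    x[j] += corr * (mi / (mi + mj))

    rng = np.random.default_rng(seed)
    if frame.velocities is not None:
        v = frame.velocities.copy()
    else:
        v = maxwell_boltzmann_velocities(masses, T, rng)
    # zero initial radial relative velocity
    d = cell.minimum_image(x[j] - x[i])
    dhat = d / np.linalg.norm(d)
    _rattle_velocity(v, i, j, mi, mj, dhat)

    ndof = max(3 * n - 3 - 1, 1)
    use_nh = T > 0 and thermostat == "nose-hoover"
    use_langevin = T > 0 and thermostat == "langevin"
    xi = 0.0
    q_t = ndof * K_B * max(T, 1.0) * EV_TO_INTERNAL * (tau_factor * dt) ** 2
    gkt = ndof * K_B * T * EV_TO_INTERNAL
    c1 = np.exp(-friction * 0.5 * dt)
    c2 = np.sqrt((1 - c1 ** 2) * K_B * T * EV_TO_INTERNAL / masses)[:, None]

    bound = potential.bind(frame.elements)
    n_steps = int(round(duration / dt))
    lam = np.empty(n_steps)
    times = (np.arange(n_steps) + 1) * dt
    max_resid = 0.0

    def thermo_half():
        nonlocal xi, v
        if use_nh:
            ke = 0.5 * (masses[:, None] * v ** 2).sum()
            xi += 0.25 * dt * (2 * ke - gkt) / q_t
            v *= np.exp(-xi * 0.5 * dt)
            ke = 0.5 * (masses[:, None] * v ** 2).sum()
            xi += 0.25 * dt * (2 * ke - gkt) / q_t
        elif use_langevin:
            v *= c1
            v += c2 * rng.normal(size=v.shape)
            d_ = cell.minimum_image(x[j] - x[i])
            _rattle_velocity(v, i, j, mi, mj, d_ / np.linalg.norm(d_))

    epot, f, _ = _forces_internal(bound, x, cell, 0)
    for step in range(1, n_steps + 1):
        thermo_half()
        v += 0.5 * dt * f / masses[:, None]
        d_old = cell.minimum_image(x[j] - x[i])
        x += dt * v
        # SHAKE: iterative position correction along the old bond vector
        for it in range(max_iter):
            d_new = cell.minimum_image(x[j] - x[i])
            r_new = np.linalg.norm(d_new)
            if abs(r_new - r_target) < tol:
                break
            g = (r_new ** 2 - r_target ** 2) / (
                2.0 * (1 / mi + 1 / mj) * np.dot(d_new, d_old))
            x[i] += (g / mi) * d_old
            x[j] -= (g / mj) * d_old
            v[i] += (g / mi) * d_old / dt
            v[j] -= (g / mj) * d_old / dt
        else:
            raise IntegrationError(
                f"step {step}: SHAKE failed to converge in {max_iter} iterations")
        max_resid = max(max_resid, abs(np.linalg.norm(
            cell.minimum_image(x[j] - x[i])) - r_target))
        epot, f, _ = _forces_internal(bound, x, cell, step)
        v += 0.5 * dt * f / masses[:, None]
        d = cell.minimum_image(x[j] - x[i])
        dhat = d / np.linalg.norm(d)
        _rattle_velocity(v, i, j, mi, mj, dhat)
        thermo_half()
        # instantaneous multiplier (see docstring for the sign convention)
        v_rel = v[j] - v[i]
        lam[step - 1] = mu * (
            (v_rel @ v_rel) / r_target
            + dhat @ (f[j] / mj - f[i] / mi)
        ) * INTERNAL_TO_EV

    burn = int(equil_frac * n_steps)
    return ConstraintResult(
        pair=(i, j), r_target=r_target,
        mean_lambda=float(lam[burn:].mean()),
        lambda_series=lam, times=times, max_residual=max_resid)


def _rattle_velocity(v, i, j, mi, mj, dhat):
    """Remove the radial component of the relative velocity of (i, j)."""
    v_rel = v[j] - v[i]
    k = (v_rel @ dhat) / (1 / mi + 1 / mj)
    v[i] += (k / mi) * dhat
    v[j] -= (k / mj) * dhat
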