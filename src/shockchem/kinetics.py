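"""Transport, free-energy, rate and shock-thermodynamics calculators.

* Mean-squared displacement with time-origin averaging and the
  ``D = slope/6`` Einstein estimator for the self-diffusion coefficient.
* Thermodynamic integration of the mean constraint force ⟨λ⟩ over the
  reaction coordinate, ``ΔF(r) = ∫_r^{r0} ⟨λ⟩ dr'`` (trapezoidal rule),
  and the barrier ΔF‡ = max ΔF.
* Transition-state-theory rate ``k = (k_B T / h) exp(-ΔF‡ / k_B T)``.
* Rankine-Hugoniot jump conditions linking (V/V0, U_p, P) at a given
  shock speed, and the production-ratio arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import Trajectory
from .units import A2_FS_TO_CM2_S, K_B, PLANCK_EV_S


# ---------------------------------------------------------------------------
# MSD / diffusion
# ---------------------------------------------------------------------------

@dataclass
class MSDCurve:
    """Mean squared displacement vs lag time."""

    lags: np.ndarray       # fs
    msd: np.ndarray        # Å²
    n_origins: np.ndarray  # origins averaged per lag
    species: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag": self.lags, "msd": self.msd,
                             "n_origins": self.n_origins})


def msd(
    trajectory: Trajectory,
    species: str | None = None,
    max_lag: int | None = None,
    origin_stride: int = 10,
    lag_stride: int = 1,
) -> MSDCurve:
    """Time-origin-averaged mean squared displacement.

    ``MSD(τ) = (1/N) Σ_i ⟨|r_i(t0+τ) - r_i(t0)|²⟩`` with origins t0
    taken every ``origin_stride`` frames, using unwrapped coordinates.
    ``max_lag`` is in frames (default: 25 % of the trajectory).
    """
    coords = trajectory.displacement_source()
    if species is not None:
        sel = trajectory.elements == species
        if not sel.any():
            raise ValueError(f"no atoms of species {species!r}")
        coords = coords[:, sel]
    n_frames = len(trajectory)
    if max_lag is None:
        max_lag = max(n_frames // 4, 1)
    if max_lag >= n_frames:
        raise ValueError("max_lag must be smaller than the trajectory length")
    dt = trajectory.dt if n_frames > 1 else 1.0
    lags = np.arange(0, max_lag + 1, lag_stride)
    out = np.zeros(len(lags))
    n_origins = np.zeros(len(lags), dtype=int)
    for k, lag in enumerate(lags):
        if lag == 0:
            n_origins[k] = len(range(0, n_frames, origin_stride))
            continue
        origins = np.arange(0, n_frames - lag, origin_stride)
        disp = coords[origins + lag] - coords[origins]
        out[k] = np.mean(np.sum(disp ** 2, axis=-1))
        n_origins[k] = len(origins)
    return MSDCurve(lags * dt, out, n_origins, species)


def diffusion_coefficient(curve: MSDCurve,
                          fit_window: tuple[float, float] = (0.2, 0.8)) -> float:
    """Self-diffusion coefficient in cm²/s from the MSD slope.

    Least-squares line (with free intercept) over the lag window given
    as fractions of the maximum lag; ``D = slope / 6`` converted from
    Å²/fs to cm²/s.
    """
    lo, hi = fit_window
    tmax = curve.lags.max()
    sel = (curve.lags >= lo * tmax) & (curve.lags <= hi * tmax)
    if sel.sum() < 3:
        raise ValueError("fit window contains fewer than 3 MSD points")
    slope = np.polyfit(curve.lags[sel], curve.msd[sel], 1)[0]
    return float(slope / 6.0 * A2_FS_TO_CM2_S)


# ---------------------------------------------------------------------------
# free energy from constrained-force integration
# ---------------------------------------------------------------------------

@dataclass
class LambdaProfile:
    """⟨λ⟩ vs constrained distance, r strictly decreasing from r0."""

    r: np.ndarray            # Å, r[0] = r0 (equilibrium, ⟨λ⟩ = 0)
    lam: np.ndarray          # eV/Å
    stderr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, float)
        self.lam = np.asarray(self.lam, float)
        if len(self.r) != len(self.lam):
            raise ValueError("r and lambda lengths differ")
        if len(self.r) >= 2 and not np.all(np.diff(self.r) < 0):
            raise ValueError("r values must be strictly decreasing from r0")

    @classmethod
    def from_table(cls, path) -> "LambdaProfile":
        df = pd.read_csv(path, sep=None, engine="python")
        cols = {c.lower(): c for c in df.columns}
        try:
            r = df[cols["r"]].to_numpy(float)
            lam = df[cols["lambda"]].to_numpy(float)
        except KeyError as exc:
            raise ValueError(f"lambda table needs columns r, lambda "
                             f"(got {list(df.columns)})") from exc
        se = df[cols["se"]].to_numpy(float) if "se" in cols else None
        return cls(r, lam, se)


@dataclass
class FreeEnergyProfile:
    """ΔF(r) relative to the equilibrium distance r0."""

    r: np.ndarray            # Å, decreasing
    delta_f: np.ndarray      # eV, ΔF(r0) = 0

    @property
    def barrier(self) -> float:
        """ΔF‡ = max ΔF over the profile, eV."""
        return float(self.delta_f.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.r, "delta_F": self.delta_f})


def free_energy_profile(profile: LambdaProfile) -> FreeEnergyProfile:
    """Integrate the mean constraint force: ``ΔF(r) = ∫_r^{r0} ⟨λ⟩ dr'``.

    Trapezoidal rule along the decreasing-r table as given; the sign
    convention makes a barrier between r0 and r_d positive.
    """
    if len(profile.r) < 3:
        raise ValueError("need at least 3 window points including r0")
    from scipy.integrate import cumulative_trapezoid
    # r decreasing: ∫_{r0}^{r} λ dr' is negative of the wanted integral
    f = -cumulative_trapezoid(profile.lam, profile.r, initial=0.0)
    return FreeEnergyProfile(profile.r.copy(), f)


def tst_rate(barrier_ev: float, T: float) -> float:
    """Transition-state-theory rate ``k = (k_B T/h) exp(-ΔF/k_B T)``, ps⁻¹."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if barrier_ev < 0:
        warnings.warn("negative barrier: rate exceeds the attempt frequency",
                      stacklevel=2)
    attempt = K_B * T / PLANCK_EV_S          # s^-1
    return attempt * np.exp(-barrier_ev / (K_B * T)) * 1e-12


# ---------------------------------------------------------------------------
# Rankine-Hugoniot jump conditions
# ---------------------------------------------------------------------------

@dataclass
class ShockState:
    """A shocked state consistent with the steady-shock jump relations."""

    rho0: float          # g/cm³
    V_s: float           # km/s
    compression: float   # V/V0
    U_p: float           # km/s
    P: float             # GPa
    P0: float            # GPa
    delta_e: float       # MJ/kg, energy jump per unit initial mass


def hugoniot_jump(
    rho0: float,
    V_s: float,
    compression: float | None = None,
    U_p: float | None = None,
    P0: float = 0.0,
) -> ShockState:
    """Solve the steady-shock jump conditions from one closure variable.

    Give either the compression ratio V/V0 or the particle velocity U_p
    (km/s); the mass condition ``U_p = Vs (1 - V/V0)`` links them, the
    momentum condition gives ``P = P0 + rho0 Vs U_p`` (GPa, with rho0 in
    g/cm³ and velocities in km/s), and the energy condition gives
    ``Δe = ½ (P + P0)(v0 - v)`` per unit initial mass (MJ/kg).
    """
    if (compression is None) == (U_p is None):
        raise ValueError("give exactly one of compression (V/V0) or U_p")
    if compression is None:
        compression = 1.0 - U_p / V_s
    else:
        U_p = V_s * (1.0 - compression)
    if not 0.0 < compression <= 1.0:
        raise ValueError("V/V0 must be in (0, 1]; rarefaction is not modeled")
    P = P0 + rho0 * V_s * U_p          # g/cm³ (km/s)² = GPa
    v0 = 1.0 / rho0                    # cm³/g
    delta_e = 0.5 * (P + P0) * v0 * (1.0 - compression)  # GPa cm³/g = MJ/kg
    return ShockState(rho0=rho0, V_s=V_s, compression=compression,
                      U_p=U_p, P=P, P0=P0, delta_e=delta_e)


def production_ratio(rate: float, reference_rate: float) -> float:
    """``100 * rate / reference``, e.g. annual NH3 yield vs Haber-Bosch."""
    if reference_rate <= 0:
        raise ValueError("reference rate must be positive")
    return 100.0 * rate / reference_rate
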