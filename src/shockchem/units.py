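"""Unit system and physical constants.

All internal quantities use Å (length), fs (time), amu (mass) and eV
(energy).  Derived conveniences: pressure in GPa, velocities in km/s,
temperature in K.  The dynamics kernels work in "internal" mechanical
units (amu, Å, fs), in which the natural energy unit is
1 amu·Å²/fs² ≈ 103.64 eV; conversion factors below are derived from
CODATA values via :mod:`scipy.constants` so that any round trip to SI
and back is an identity to floating-point precision.
"""

from __future__ import annotations

from scipy import constants as _c

# --- fundamental constants -------------------------------------------------
#: Boltzmann constant, eV/K
K_B = _c.physical_constants["Boltzmann constant in eV/K"][0]
#: Planck constant, eV*s
PLANCK_EV_S = _c.physical_constants["Planck constant in eV/Hz"][0]

AMU_KG = _c.atomic_mass
EV_J = _c.electron_volt

# --- conversion factors ----------------------------------------------------
#: 1 amu*Å²/fs² expressed in eV (≈ 103.6427)
INTERNAL_TO_EV = AMU_KG * 1e10 / EV_J
EV_TO_INTERNAL = 1.0 / INTERNAL_TO_EV

#: 1 eV/Å³ expressed in GPa (≈ 160.2177)
GPA_PER_EV_A3 = EV_J / 1e-30 / 1e9
#: 1 amu/(Å*fs²) (internal pressure) expressed in GPa
GPA_PER_INTERNAL_P = INTERNAL_TO_EV * GPA_PER_EV_A3

KMS_TO_A_FS = 1e-2
A_FS_TO_KMS = 1e2

#: Å²/fs -> cm²/s  (1e-16 cm² / 1e-15 s)
A2_FS_TO_CM2_S = 0.1
CM2_S_TO_A2_FS = 10.0

#: 1 amu/Å³ expressed in g/cm³ (≈ 1.66054)
G_CM3_PER_AMU_A3 = AMU_KG * 1e3 / 1e-24

# SI factors per internal unit, keyed by quantity name.
_SI_FACTOR = {
    "length": 1e-10,                 # Å -> m
    "time": 1e-15,                   # fs -> s
    "mass": AMU_KG,                  # amu -> kg
    "energy": EV_J,                  # eV -> J
    "pressure": 1e9,                 # GPa -> Pa
    "velocity": 1e3,                 # km/s -> m/s
    "temperature": 1.0,              # K -> K
}


def to_si(value: float, quantity: str) -> float:
    """Convert *value* from the package unit for *quantity* to SI."""
    try:
        return value * _SI_FACTOR[quantity]
    except KeyError:
        raise KeyError(f"unknown quantity {quantity!r}") from None


def from_si(value: float, quantity: str) -> float:
    """Inverse of :func:`to_si`."""
    try:
        return value / _SI_FACTOR[quantity]
    except KeyError:
        raise KeyError(f"unknown quantity {quantity!r}") from None


# IUPAC 2021 standard atomic weights (abridged), amu.
ATOMIC_MASSES = {
    "H": 1.008,
    "He": 4.002602,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Ne": 20.1797,
    "Na": 22.98976928,
    "Mg": 24.305,
    "Al": 26.9815384,
    "Si": 28.085,
    "P": 30.973761998,
    "S": 32.06,
    "Cl": 35.45,
    "Ar": 39.95,
    "K": 39.0983,
    "Ca": 40.078,
    "Ti": 47.867,
    "Cr": 51.9961,
    "Mn": 54.938043,
    "Fe": 55.845,
    "Co": 58.933194,
    "Ni": 58.6934,
    "Cu": 63.546,
    "Zn": 65.38,
}


def mass_of(element: str) -> float:
    """Standard atomic weight of *element* in amu."""
    try:
        return ATOMIC_MASSES[element]
    except KeyError:
        raise KeyError(f"no tabulated mass for element {element!r}") from None
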