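"""Shared fixtures.

The expensive simulation fixtures (the 4 ps scripted reactive
trajectory and the two-phase MSST shock run) are session-scoped so the
unit tests and the acceptance tests analyze the same runs instead of
recomputing them.
"""

import numpy as np
import pytest

import shockchem as sc
from shockchem.dynamics import msst_states_to_frame, run_msst


@pytest.fixture(scope="session")
def lj_argon():
    """3x3x3 fcc LJ argon crystal at its zero-stress lattice constant."""
    frame, pot = sc.lj_crystal((3, 3, 3))
    return frame, pot


@pytest.fixture(scope="session")
def stiff_lj_solid():
    """2x2x2 fcc crystal with a 0.1 eV well: solid at 300 K."""
    frame, pot = sc.lj_crystal((2, 2, 2), epsilon=0.1, sigma=3.0)
    return frame, pot


@pytest.fixture(scope="session")
def reference_system():
    """The 182-atom Fe36/16 N2/38 H2O frame plus molecule bookkeeping."""
    return sc.build_initial_system_info(seed=0)


@pytest.fixture(scope="session")
def nh3_run(reference_system):
    """4 ps scripted trajectory with the three NH3 formations, analyzed."""
    frame, info = reference_system
    script = sc.nh3_formation_script(frame, info, seed=7)
    traj = sc.script_reactive_trajectory(frame, script, duration=4000.0,
                                         dt=0.242)
    bonds = sc.detect_bonds(traj)
    return frame, script, traj, bonds


@pytest.fixture(scope="session")
def msst_run(lj_argon):
    """Two-phase MSST shock of the LJ crystal at Vs = 4 km/s.

    Phase A relaxes onto the compressed Rayleigh-line state with cell
    damping; phase B continues undamped from that state.  Returns
    (frame, P0, phase-B state table).
    """
    frame, pot = lj_argon
    V0 = frame.cell.volume
    traj_a, st_a = run_msst(frame, pot, V_s=4.0, dt=0.242, n_steps=4000,
                            T0=30.0, seed=1, initial_vdot=-2e-3 * V0,
                            cell_damping=0.2)
    p0 = traj_a.metadata["P0"]
    frame_b = traj_a.frame(len(traj_a) - 1)
    _, st_b = run_msst(frame_b, pot, V_s=4.0, dt=0.242, n_steps=4000,
                       T0=30.0, seed=2, P0=p0, V0_ref=V0,
                       initial_vdot=st_a[-1].V_dot)
    return frame, p0, msst_states_to_frame(st_b)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
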