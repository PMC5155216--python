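import numpy as np
import pytest

import shockchem as sc
from shockchem.dynamics import (constrained_window, maxwell_boltzmann_velocities,
                                run_msst, run_nve, run_nvt)


class TestNVT:
    def test_kinetic_temperature_averages_to_target(self, stiff_lj_solid):
        frame, pot = stiff_lj_solid
        traj = run_nvt(frame, pot, T=300.0, dt=0.5, n_steps=8000, seed=3,
                       stride=10)
        energy = traj.metadata["energy"]
        half = energy.iloc[len(energy) // 2:]
        blocks = np.array([b.mean() for b in
                           np.array_split(half["T"].to_numpy(), 8)])
        se = blocks.std(ddof=1) / np.sqrt(len(blocks))
        assert abs(half["T"].mean() - 300.0) < 3 * max(se, 1.0)

    def test_zero_temperature_equilibrium_is_stationary(self, lj_argon):
        frame, pot = lj_argon
        f0 = sc.Frame(frame.elements, frame.positions, frame.cell,
                      velocities=np.zeros((frame.n_atoms, 3)))
        traj = run_nvt(f0, pot, T=None, dt=0.242, n_steps=50)
        np.testing.assert_allclose(traj.positions[-1], traj.positions[0],
                                   atol=1e-10)

    def test_identical_seeds_are_bit_identical(self, stiff_lj_solid):
        frame, pot = stiff_lj_solid
        a = run_nvt(frame, pot, T=200.0, dt=0.5, n_steps=200, seed=42)
        b = run_nvt(frame, pot, T=200.0, dt=0.5, n_steps=200, seed=42)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)


@pytest.fixture(scope="module")
def nve_run(stiff_lj_solid):
    frame, pot = stiff_lj_solid
    rng = np.random.default_rng(5)
    f0 = sc.Frame(frame.elements, frame.positions, frame.cell,
                  velocities=maxwell_boltzmann_velocities(
                      frame.masses(), 80.0, rng))
    return frame, run_nve(f0, pot, dt=0.242, n_steps=8264, stride=50)


class TestNVE:
    def test_energy_drift_small(self, nve_run):
        frame, traj = nve_run
        e = traj.metadata["energy"]
        etot = (e.E_kin + e.E_pot).to_numpy()
        drift = abs(etot[-1] - etot[0]) / frame.n_atoms / (e.t.iloc[-1] / 1000)
        assert drift < 1e-5   # eV/atom/ps at dt = 0.242 fs

    def test_momentum_conserved_to_machine_precision(self, nve_run):
        frame, traj = nve_run
        m = frame.masses()[:, None]
        p0 = (m * traj.velocities[0]).sum(axis=0)
        p1 = (m * traj.velocities[-1]).sum(axis=0)
        assert np.abs(p1 - p0).max() < 1e-12


class TestMSST:
    def test_unshocked_fixed_point(self):
        cell = sc.SimulationCell.orthorhombic(10, 10, 10)
        frame = sc.Frame(["Ar"] * 4, [[1, 1, 1], [5, 1, 1], [1, 5, 1],
                                      [1, 1, 5]], cell)
        _, states = run_msst(frame, sc.ZeroPotential(), V_s=5.0, n_steps=200,
                             T0=0.0, P0=0.0, initial_vdot=0.0)
        assert all(s.V_dot == 0.0 for s in states)
        assert all(s.U_p == 0.0 for s in states)
        assert states[-1].compression == 1.0

    def test_stationary_state_sits_on_rayleigh_line(self, msst_run):
        frame, p0, table = msst_run
        rho0 = frame.masses().sum() / frame.cell.volume
        p_ray = sc.rayleigh_pressure(rho0, 4.0, table.V_over_V0.mean(),
                                     P0_gpa=p0)
        assert abs(table.P.mean() - p_ray) / p_ray < 0.02
        assert table.V_over_V0.mean() < 0.95   # genuinely compressed

    def test_extended_energy_conserved(self, msst_run):
        frame, _, table = msst_run
        e = table.E_cons.to_numpy()
        span_ps = (table.t.iloc[-1] - table.t.iloc[0]) / 1000
        drift = abs(e[-1] - e[0]) / frame.n_atoms / span_ps
        assert drift < 1e-4

    def test_up_diagnostic_is_mass_jump_identity(self, msst_run):
        _, _, table = msst_run
        np.testing.assert_allclose(table.U_p, 4.0 * (1 - table.V_over_V0),
                                   rtol=1e-12)

    def test_small_cell_mass_warns(self, lj_argon):
        frame, pot = lj_argon
        with pytest.warns(UserWarning, match="Q is small"):
            run_msst(frame, pot, V_s=4.0, Q=1e-4, n_steps=1, T0=0.0, P0=0.0,
                     initial_vdot=0.0)

    def test_requires_orthorhombic_cell(self):
        h = np.eye(3) * 10.0
        h[0, 1] = 1.0
        frame = sc.Frame(["Ar"], [[1, 1, 1]], sc.SimulationCell(h))
        with pytest.raises(ValueError, match="orthorhombic"):
            run_msst(frame, sc.ZeroPotential(), V_s=5.0, n_steps=1)


class TestConstrainedWindow:
    k0, r0 = 5.0, 1.5

    def _pair(self, r, cold=True):
        cell = sc.SimulationCell.orthorhombic(20, 20, 20)
        vel = np.zeros((2, 3)) if cold else None   # None: seeded MB draw
        return sc.Frame(["N", "H"], [[10, 10, 10], [10 + r, 10, 10]], cell,
                        velocities=vel)

    def _pot(self):
        return sc.HarmonicBondPotential([(0, 1, self.k0, self.r0)])

    def test_zero_multiplier_at_equilibrium_distance(self):
        res = constrained_window(self._pair(self.r0), self._pot(), (0, 1),
                                 self.r0, T=0.0, duration=50.0)
        assert res.mean_lambda == pytest.approx(0.0, abs=1e-10)

    def test_harmonic_multiplier_in_cold_limit(self):
        # constrained at r0 - delta the mean force is +k0*delta
        delta = 0.2
        res = constrained_window(self._pair(self.r0 - delta), self._pot(),
                                 (0, 1), self.r0 - delta, T=0.0, duration=50.0)
        assert res.mean_lambda == pytest.approx(self.k0 * delta, rel=1e-6)

    def test_constraint_residual_below_tolerance(self):
        res = constrained_window(self._pair(1.35, cold=False), self._pot(),
                                 (0, 1), 1.3, T=300.0, duration=200.0,
                                 seed=11)
        assert res.max_residual < 1e-8

    def test_longer_window_shrinks_standard_error(self):
        # doubling the window should shrink the seed-to-seed scatter of
        # the mean multiplier by about sqrt(2).  The Langevin thermostat
        # makes the multiplier series mixing, so the 1/sqrt(duration)
        # law holds even for this near-integrable two-atom system (a
        # single Nosé-Hoover chain on it is not ergodic).
        def scatter(duration):
            means = [constrained_window(
                self._pair(1.3, cold=False), self._pot(), (0, 1), 1.3,
                T=300.0, duration=duration, seed=s,
                thermostat="langevin").mean_lambda for s in range(16)]
            return np.std(means, ddof=1)

        ratio = scatter(400.0) / scatter(800.0)
        assert 1.1 < ratio < 1.9

    def test_initial_distance_must_be_near_target(self):
        with pytest.raises(ValueError, match="0.5"):
            constrained_window(self._pair(2.5), self._pot(), (0, 1), 1.3,
                               T=0.0, duration=10.0)
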