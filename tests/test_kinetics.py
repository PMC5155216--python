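import numpy as np
import pytest

import shockchem as sc
from shockchem.kinetics import MSDCurve
from shockchem.units import K_B, PLANCK_EV_S


class TestMSD:
    def test_stationary_atoms_have_zero_msd(self):
        cell = sc.SimulationCell.orthorhombic(10, 10, 10)
        pos = np.ones((50, 4, 3))
        traj = sc.Trajectory(["Fe"] * 4, np.arange(50) * 1.0, pos,
                             [cell] * 50, wrap=False)
        curve = sc.msd(traj, max_lag=12)
        np.testing.assert_allclose(curve.msd, 0.0)

    def test_ballistic_motion_is_quadratic(self):
        cell = sc.SimulationCell.orthorhombic(1e4, 1e4, 1e4)
        v = 0.37
        t = np.arange(100) * 1.0
        pos = np.zeros((100, 2, 3))
        pos[:, :, 0] = (v * t)[:, None]
        traj = sc.Trajectory(["Fe", "Fe"], t, pos, [cell] * 100, wrap=False)
        curve = sc.msd(traj, max_lag=25, origin_stride=5)
        np.testing.assert_allclose(curve.msd, v ** 2 * curve.lags ** 2,
                                   rtol=1e-10)

    def test_msd_slope_recovers_brownian_d(self):
        spec = sc.BrownianSpec(seed=17)
        traj = sc.brownian_trajectory(spec)
        curve = sc.msd(traj, species="Fe", origin_stride=10, lag_stride=8)
        d = sc.diffusion_coefficient(curve)
        assert d == pytest.approx(spec.D, rel=0.25)

    def test_missing_species_rejected(self):
        traj = sc.brownian_trajectory(sc.BrownianSpec(duration=20))
        with pytest.raises(ValueError, match="species"):
            sc.msd(traj, species="Na")


class TestDiffusionCoefficient:
    def test_exact_line_returns_exact_d(self):
        # MSD = 6 D tau with the 5 km/s shocked-iron value
        d_true = 2.35e-5
        lags = np.linspace(0, 2000, 200)
        curve = MSDCurve(lags, 6 * (d_true * 10) * lags,
                         np.ones(200, dtype=int))
        assert sc.diffusion_coefficient(curve) == pytest.approx(d_true,
                                                                rel=1e-12)

    def test_zero_msd_gives_zero_d(self):
        lags = np.linspace(0, 100, 50)
        curve = MSDCurve(lags, np.zeros(50), np.ones(50, dtype=int))
        assert sc.diffusion_coefficient(curve) == 0.0

    def test_short_window_rejected(self):
        curve = MSDCurve(np.array([0.0, 1.0, 2.0]), np.zeros(3),
                         np.ones(3, dtype=int))
        with pytest.raises(ValueError, match="3"):
            sc.diffusion_coefficient(curve, fit_window=(0.9, 1.0))


class TestFreeEnergyProfile:
    def test_zero_mean_force_gives_flat_profile(self):
        r = np.linspace(2.0, 1.0, 11)
        fep = sc.free_energy_profile(sc.LambdaProfile(r, np.zeros(11)))
        np.testing.assert_allclose(fep.delta_f, 0.0)
        assert fep.barrier == 0.0

    def test_harmonic_mean_force_integrates_to_quadratic(self):
        k0, r0 = 3.0, 2.0
        r = np.linspace(r0, 1.0, 41)
        fep = sc.free_energy_profile(sc.LambdaProfile(r, k0 * (r0 - r)))
        np.testing.assert_allclose(fep.delta_f, 0.5 * k0 * (r0 - r) ** 2,
                                   atol=1e-3)   # trapezoid error bound

    def test_linear_in_lambda_scaling(self):
        rng = np.random.default_rng(2)
        r = np.linspace(2.0, 1.0, 15)
        lam = rng.normal(size=15)
        f1 = sc.free_energy_profile(sc.LambdaProfile(r, lam)).delta_f
        f3 = sc.free_energy_profile(sc.LambdaProfile(r, 3 * lam)).delta_f
        np.testing.assert_allclose(f3, 3 * f1, rtol=1e-12)

    def test_barrier_of_reference_profile(self):
        # profile shaped to integrate to the 0.09 eV activation energy
        r0, rd = 2.0, 1.0
        r = np.linspace(r0, rd, 201)
        lam = np.sin(np.pi * (r0 - r) / (r0 - rd))
        lam *= 0.09 / (2 * (r0 - rd) / np.pi)
        fep = sc.free_energy_profile(sc.LambdaProfile(r, lam))
        assert fep.barrier == pytest.approx(0.09, abs=1e-4)

    def test_unordered_r_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            sc.LambdaProfile(np.array([1.0, 2.0, 1.5]), np.zeros(3))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            sc.free_energy_profile(
                sc.LambdaProfile(np.array([2.0, 1.0]), np.zeros(2)))


class TestTSTRate:
    def test_attempt_frequency_limit(self):
        assert sc.tst_rate(0.0, 1500.0) == pytest.approx(
            K_B * 1500.0 / PLANCK_EV_S * 1e-12, rel=1e-12)

    def test_monotone_in_temperature_and_barrier(self):
        rates_t = [sc.tst_rate(0.09, t) for t in (600, 1200, 2100, 3000)]
        assert np.all(np.diff(rates_t) > 0)
        rates_b = [sc.tst_rate(b, 1200.0) for b in (0.0, 0.05, 0.09, 0.2)]
        assert np.all(np.diff(rates_b) < 0)

    def test_negative_barrier_warns(self):
        with pytest.warns(UserWarning, match="attempt frequency"):
            sc.tst_rate(-0.1, 300.0)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            sc.tst_rate(0.09, 0.0)


class TestHugoniotJump:
    def test_jump_relations_hold_jointly(self):
        st = sc.hugoniot_jump(2.386, 5.0, compression=0.58, P0=0.5)
        assert st.U_p == pytest.approx(5.0 * (1 - st.compression), rel=1e-14)
        assert st.P == pytest.approx(st.P0 + st.rho0 * st.V_s * st.U_p,
                                     rel=1e-14)
        assert st.delta_e == pytest.approx(
            0.5 * (st.P + st.P0) * (1 / st.rho0) * (1 - st.compression),
            rel=1e-14)

    def test_no_shock_limit(self):
        st = sc.hugoniot_jump(2.386, 5.0, U_p=0.0, P0=1.3)
        assert st.P == st.P0 and st.delta_e == 0.0 and st.compression == 1.0

    def test_exactly_one_closure_variable(self):
        with pytest.raises(ValueError):
            sc.hugoniot_jump(2.386, 5.0)
        with pytest.raises(ValueError):
            sc.hugoniot_jump(2.386, 5.0, compression=0.6, U_p=2.0)

    def test_rarefaction_rejected(self):
        with pytest.raises(ValueError, match="rarefaction"):
            sc.hugoniot_jump(2.386, 5.0, compression=1.2)


class TestProductionRatio:
    def test_identity_and_scaling(self):
        assert sc.production_ratio(3.0, 3.0) == 100.0
        assert sc.production_ratio(4.3e7, 1.59e8) == pytest.approx(27.0,
                                                                   abs=0.1)

    def test_reference_must_be_positive(self):
        with pytest.raises(ValueError):
            sc.production_ratio(1.0, 0.0)
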