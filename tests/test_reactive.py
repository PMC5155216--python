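import numpy as np
import pandas as pd
import pytest

import shockchem as sc
from shockchem.reactive import (BondCriteria, DEFAULT_VALENCE, NAMED_SPECIES,
                                _lifetime_filter, pair_key)


def two_atom_traj(distances, elements=("H", "O"), dt=0.242, box=30.0):
    """Trajectory of one pair whose separation follows *distances*."""
    n = len(distances)
    cell = sc.SimulationCell.orthorhombic(box, box, box)
    pos = np.zeros((n, 2, 3))
    pos[:, 1, 0] = distances
    pos[:, :, :] += 1.0
    return sc.Trajectory(list(elements), np.arange(n) * dt, pos, [cell] * n)


class TestBondCriteria:
    def test_lifetime_in_frames(self):
        crit = BondCriteria()
        assert crit.frames_required(0.242) == 10
        assert crit.frames_required(2.42) == 1

    def test_incommensurate_timestep_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            BondCriteria().frames_required(0.7)

    def test_unordered_pair_keys(self):
        crit = BondCriteria()
        assert crit.cutoffs[pair_key("O", "H")] == 1.25
        assert crit.cutoffs[pair_key("H", "O")] == 1.25


class TestDetectBonds:
    def test_bond_appears_when_lifetime_window_completes(self):
        # within cutoff for exactly 10 frames at dt = 0.242 (L = 10):
        # the bond exists at the 10th in-cutoff frame only
        d = [1.0] * 10 + [5.0] * 5
        bonds = sc.detect_bonds(two_atom_traj(d))
        counts = bonds.counts(("H", "O"))
        expected = np.zeros(15, dtype=int)
        expected[9] = 1
        np.testing.assert_array_equal(counts, expected)

    def test_nine_frames_never_bond(self):
        d = [1.0] * 9 + [5.0] * 6
        bonds = sc.detect_bonds(two_atom_traj(d))
        assert sc.count_bonds(bonds, ("H", "O")).sum() == 0

    def test_drops_immediately_on_excursion(self):
        d = [1.0] * 12 + [5.0] + [1.0] * 12
        counts = sc.detect_bonds(two_atom_traj(d)).counts(("H", "O"))
        assert counts[11] == 1 and counts[12] == 0
        # re-forms only after a fresh 10-frame window
        assert counts[13:22].sum() == 0 and counts[22] == 1

    def test_lifetime_filter_matches_sliding_window_oracle(self, rng):
        # randomized occupancy vs an exhaustive all() over each window
        for L in (1, 3, 10):
            within = rng.random((50, 7)) < 0.7
            fast = _lifetime_filter(within, L)
            brute = np.zeros_like(within)
            for t in range(50):
                if t >= L - 1:
                    brute[t] = within[t - L + 1: t + 1].all(axis=0)
            np.testing.assert_array_equal(fast, brute)

    def test_unit_lifetime_reduces_to_cutoff_criterion(self, rng):
        n = 30
        cell = sc.SimulationCell.orthorhombic(8, 8, 8)
        pos = rng.uniform(0, 8, (n, 6, 3))
        traj = sc.Trajectory(["H", "H", "H", "O", "O", "O"],
                             np.arange(n) * 2.42, pos, [cell] * n)
        crit = BondCriteria(cutoffs={("H", "O"): 1.8}, lifetime=2.42)
        counts = sc.detect_bonds(traj, crit).counts(("H", "O"))
        for t in range(n):
            frame = traj.frame(t)
            naive = sum(
                sc.minimum_image_distance(frame, i, j) <= 1.8
                for i in range(3) for j in range(3, 6))
            assert counts[t] == naive

    def test_filtered_counts_never_exceed_unfiltered(self, nh3_run):
        *_, bonds = nh3_run
        for key, ptb in bonds.per_type.items():
            assert np.all(bonds.counts(key) <= bonds.unfiltered_counts(key))

    def test_intact_waters_give_76_oh_bonds(self, reference_system):
        frame, _ = reference_system
        n = 20
        rng = np.random.default_rng(0)
        pos = frame.positions[None] + rng.normal(scale=0.02,
                                                 size=(n, frame.n_atoms, 3))
        traj = sc.Trajectory(frame.elements, np.arange(n) * 0.242, pos,
                             [frame.cell] * n)
        counts = sc.detect_bonds(traj).counts(("H", "O"))
        assert counts[-1] == 76   # 2 bonds per intact H2O, 38 waters

    def test_isolated_atoms_have_no_bonds(self):
        cell = sc.SimulationCell.orthorhombic(30, 30, 30)
        pos = np.tile((np.arange(4) * 6.0)[None, :, None], (12, 1, 3))
        traj = sc.Trajectory(["H", "O", "N", "Fe"], np.arange(12) * 0.242,
                             pos, [cell] * 12)
        bonds = sc.detect_bonds(traj)
        assert all(bonds.counts(k).sum() == 0 for k in bonds.per_type) or \
            not bonds.per_type


class TestSpeciesCensus:
    def _bonds(self, elements, distances_fn, n_frames=12):
        cell = sc.SimulationCell.orthorhombic(30, 30, 30)
        pos = np.tile(distances_fn()[None], (n_frames, 1, 1))
        traj = sc.Trajectory(elements, np.arange(n_frames) * 0.242, pos,
                             [cell] * n_frames)
        return sc.detect_bonds(traj)

    def test_isolated_nh3(self):
        def geom():
            p = np.full((4, 3), 10.0)
            p[1] += [1.0, 0, 0]
            p[2] += [0, 1.0, 0]
            p[3] += [0, 0, 1.0]
            return p

        census = sc.species_census(self._bonds(["N", "H", "H", "H"], geom), 11)
        assert census.species_count("NH3") == 1

    def test_hydrazinium_like_chain(self):
        def geom():
            # N2H5: two bonded N, 3 H on one, 2 H on the other
            p = np.full((7, 3), 10.0)
            p[1] += [1.2, 0, 0]                       # N-N
            p[2] += [-0.8, 0.5, 0]
            p[3] += [0, 1.0, 0]
            p[4] += [0, 0, 1.0]
            p[5] += [2.0, 0.5, 0]
            p[6] += [1.2, 0, 1.0]
            return p

        census = sc.species_census(
            self._bonds(["N", "N", "H", "H", "H", "H", "H"], geom), 11)
        assert census.species_count("N2H5") == 1
        assert dict(NAMED_SPECIES["N2H5"]) == {"N": 2, "H": 5}

    def test_census_conserves_composition_on_random_graphs(self, rng):
        elements = np.array(["H", "N", "O", "Fe"])[
            rng.integers(0, 4, size=40)]
        cell = sc.SimulationCell.orthorhombic(12, 12, 12)
        for _ in range(20):
            pos = np.tile(rng.uniform(0, 12, (40, 3))[None], (12, 1, 1))
            traj = sc.Trajectory(elements, np.arange(12) * 0.242, pos,
                                 [cell] * 12)
            bonds = sc.detect_bonds(traj)
            census = sc.species_census(bonds, 11)
            assert dict(census.total_composition()) == traj.composition()


class TestFormationEvents:
    def test_protonation_does_not_decrement(self, reference_system):
        frame, info = reference_system
        script = sc.nh3_formation_script(frame, info, times_ps=(0.7,),
                                         protonate=True, seed=7)
        traj = sc.script_reactive_trajectory(frame, script, duration=900.0)
        bonds = sc.detect_bonds(traj)
        events, cumulative = sc.cumulative_formation_events(bonds, "NH3")
        assert len(events) == 1
        assert cumulative[-1] == 1                      # still counted as NH4
        assert np.all(np.diff(cumulative) >= 0)         # monotone
        census = sc.species_census(bonds, len(traj) - 1)
        assert census.species_count("NH4") == 1
        assert census.species_count("NH3") == 0

    def test_no_nh_bonds_no_events(self):
        cell = sc.SimulationCell.orthorhombic(30, 30, 30)
        pos = np.tile((np.arange(4) * 7.0)[None, :, None], (12, 1, 3))
        traj = sc.Trajectory(["N", "N", "H", "H"], np.arange(12) * 0.242,
                             pos, [cell] * 12)
        events, cumulative = sc.cumulative_formation_events(
            sc.detect_bonds(traj), "NH3")
        assert events == [] and cumulative.sum() == 0


class TestPartialRDF:
    def test_ideal_gas_normalizes_to_one(self, rng):
        cell = sc.SimulationCell.orthorhombic(20, 20, 20)
        n_frames, n_atoms = 40, 120
        pos = rng.uniform(0, 20, (n_frames, n_atoms, 3))
        traj = sc.Trajectory(["Ar"] * n_atoms, np.arange(n_frames) * 1.0,
                             pos, [cell] * n_frames)
        g = sc.partial_rdf(traj, ("Ar", "Ar"), bin_width=0.25, r_max=8.0)
        tail = g[g.r > 2.0]["g"]
        assert abs(tail.mean() - 1.0) < 0.05

    def test_crystal_first_peak_at_nearest_neighbour(self, lj_argon):
        frame, _ = lj_argon
        traj = sc.Trajectory(frame.elements, [0.0], frame.positions[None],
                             [frame.cell])
        g = sc.partial_rdf(traj, ("Ar", "Ar"), bin_width=0.05, r_max=7.0)
        a = frame.cell.h[0, 0] / 3
        assert g.r[g.g.idxmax()] == pytest.approx(a / np.sqrt(2), abs=0.05)

    def test_missing_elements_rejected(self, lj_argon):
        frame, _ = lj_argon
        traj = sc.Trajectory(frame.elements, [0.0], frame.positions[None],
                             [frame.cell])
        with pytest.raises(ValueError, match="no atoms"):
            sc.partial_rdf(traj, ("H", "O"))

    def test_first_minimum_of_synthetic_bimodal(self):
        # two equal-width Gaussian peaks; the analytic valley is midway,
        # placed at the H-O cutoff value used throughout
        r = np.arange(0.025, 3.0, 0.05)
        g = np.exp(-(r - 0.95) ** 2 / 0.02) + np.exp(-(r - 1.55) ** 2 / 0.02)
        assert sc.first_minimum(pd.DataFrame({"r": r, "g": g})) == \
            pytest.approx(1.25, abs=0.051)


class TestMullikenCharge:
    def test_neutral_and_reduced_atoms(self):
        elements = ["N", "H", "O", "Fe"]
        z0 = np.array([DEFAULT_VALENCE[e] for e in elements])
        q = sc.mulliken_charge(elements, z0[None, :])
        np.testing.assert_allclose(q, 0.0)
        # reduced nitrogen carries negative charge
        q = sc.mulliken_charge(["N"], np.array([[5.4]]))
        assert q[0, 0] == pytest.approx(-0.4)

    def test_total_charge_conserved_when_population_is(self, rng):
        elements = ["N", "O", "H", "H", "Fe"]
        z0 = np.array([DEFAULT_VALENCE[e] for e in elements])
        flows = rng.normal(size=(30, 5))
        flows -= flows.mean(axis=1, keepdims=True)   # redistribution only
        z = z0[None, :] + flows
        q = sc.mulliken_charge(elements, z)
        np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_unknown_element_rejected(self):
        with pytest.raises(KeyError, match="Xe"):
            sc.mulliken_charge(["Xe"], np.array([[1.0]]))
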