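import math

import numpy as np
import pytest

import dnarray as da
from dnarray.errors import DegenerateInputError, DomainError
from dnarray.io import Frame, Topology, Trajectory
from dnarray.synth import imposed_eta1
from dnarray.water import (PairAxisFrame, epsilon_from_gk, kf_rhs, kirkwood_gk,
                           q4_random_gas, q4_tetrahedrality)


def water_traj(pos, dip, box=(10.0, 10.0, 3.4), times=None):
    n = pos[0].shape[0]
    top = Topology(ids=np.arange(n), kinds=np.full(n, "water", dtype=object),
                   mol_ids=np.arange(n), charges=np.zeros(n))
    frames = [Frame(time=float(t if times is None else times[t]),
                    box=np.array(box), pos=p, dipole=d)
              for t, (p, d) in enumerate(zip(pos, dip))]
    return Trajectory(topology=top, frames=frames)


class TestEtaProfiles:
    def pair_frame(self):
        return PairAxisFrame(origin=np.array([0.0, 0.0]),
                             axis=np.array([1.0, 0.0]), spacing=2.0)

    def test_aligned_dipoles_give_eta1_eta2_one(self):
        pos = np.column_stack([np.linspace(0.1, 1.9, 40),
                               np.zeros(40), np.zeros(40)])
        dip = np.tile([0.05, 0.0, 0.0], (40, 1))
        traj = water_traj([pos], [dip])
        prof = da.eta_profiles(traj, self.pair_frame(), n_bins=5, n_boot=10)
        np.testing.assert_allclose(prof.eta1, 1.0)
        np.testing.assert_allclose(prof.eta2, 1.0)

    def test_perpendicular_dipoles_give_eta2_minus_half(self):
        pos = np.column_stack([np.linspace(0.1, 1.9, 40),
                               np.zeros(40), np.zeros(40)])
        dip = np.tile([0.0, 0.0, 0.05], (40, 1))
        traj = water_traj([pos], [dip])
        prof = da.eta_profiles(traj, self.pair_frame(), n_bins=5, n_boot=10)
        np.testing.assert_allclose(prof.eta1, 0.0, atol=1e-12)
        np.testing.assert_allclose(prof.eta2, -0.5)

    def test_empty_bins_flagged_not_fabricated(self):
        pos = np.array([[0.1, 0.0, 0.0]])
        dip = np.array([[0.05, 0.0, 0.0]])
        traj = water_traj([pos], [dip])
        prof = da.eta_profiles(traj, self.pair_frame(), n_bins=10, n_boot=5)
        assert prof.population[0] == 1
        assert np.all(prof.population[1:] == 0)
        assert np.all(np.isnan(prof.eta1[1:]))

    def test_profile_recovery_within_3se(self, water_pair, hex_lattice):
        traj, (i1, i2) = water_pair
        pf = PairAxisFrame.from_lattice(hex_lattice, i1, i2)
        prof = da.eta_profiles(traj, pf, n_bins=20, seed=1)
        target = imposed_eta1(prof.bin_centers * pf.spacing, pf.spacing, 0.5, 0.2)
        assert np.all(np.abs(prof.eta1 - target) < 3.0 * prof.eta1_sd)

    def test_pair_swap_negates_eta1_keeps_eta2(self, water_pair, hex_lattice):
        """Exact mirror identity on the same waters viewed from the other DNA."""
        traj, (i1, i2) = water_pair
        pf = PairAxisFrame.from_lattice(hex_lattice, i1, i2)
        a = da.eta_profiles(traj, pf, n_bins=20, seed=1)
        b = da.eta_profiles(traj, pf.swapped(), n_bins=20, seed=1)
        np.testing.assert_allclose(b.eta1, -a.eta1[::-1], atol=1e-12)
        np.testing.assert_allclose(b.eta2, a.eta2[::-1], atol=1e-12)
        np.testing.assert_allclose(b.eta3, a.eta3[::-1], atol=1e-12)

    def test_eta3_nonzero_for_isotropic_dipoles(self, hex_lattice):
        p = da.WaterProfileParams(pair_axis=(0, 1), n_water=2000,
                                  eta1_surface=0.0, decay_length=0.2,
                                  n_frames=2, seed=3)
        traj = da.gen_water_between_pair(p, hex_lattice)
        pf = PairAxisFrame.from_lattice(hex_lattice, 0, 1)
        prof = da.eta_profiles(traj, pf, n_bins=4, n_boot=20)
        assert np.all(prof.eta3 > 0)


class TestQ4:
    def test_perfect_tetrahedron_is_exactly_one(self):
        fr = da.gen_tetrahedral_fixture(0.0)
        assert q4_tetrahedrality(fr, [0], [1, 2, 3, 4])[0] == pytest.approx(1.0, abs=1e-12)

    def test_collinear_degenerate_is_minus_three(self):
        fr = da.gen_tetrahedral_fixture(0.0, degenerate=True)
        assert q4_tetrahedrality(fr, [0], [1, 2, 3, 4])[0] == pytest.approx(-3.0, abs=1e-12)

    def test_random_gas_mean_zero(self):
        vals = q4_random_gas(100000, seed=7)
        assert abs(vals.mean()) < 0.01
        assert np.all(vals <= 1.0)

    def test_fewer_than_four_candidates_skipped(self):
        fr = da.gen_tetrahedral_fixture(0.0)
        out = q4_tetrahedrality(fr, [0], [1, 2, 3])
        assert np.isnan(out[0])

    def test_z_periodic_minimum_image(self):
        # neighbor across the z boundary must be seen as near
        pos = np.array([[5.0, 5.0, 0.05],
                        [5.0, 5.0, 3.35],   # 0.1 away through the boundary
                        [5.28, 5.0, 0.05], [5.0, 5.28, 0.05], [4.72, 5.0, 0.05],
                        [5.9, 5.9, 1.4]])   # far, oblique: swapped in otherwise
        fr = Frame(time=0.0, box=np.array([10.0, 10.0, 3.4]), pos=pos)
        q_per = q4_tetrahedrality(fr, [0], list(range(1, 6)), z_period=3.4)
        q_non = q4_tetrahedrality(fr, [0], list(range(1, 6)))
        assert not np.isclose(q_per[0], q_non[0])


def test_acceptor_candidates_mix_waters_and_phosphates():
    """Q4 neighbor pool: waters plus flagged electronegative DNA sites."""
    from dnarray.water import acceptor_candidates

    ions = da.gen_counterions(2, 2, 1, box=[8.0, 8.0, 3.4], seed=0)
    idx = acceptor_candidates(ions.topology)
    kinds = ions.topology.kinds[idx]
    assert np.all(kinds == "dna_site")          # no waters in this system
    assert len(idx) == 40                       # 2 DNA x 20 phosphates
    assert not np.any(np.isin(["na", "cl", "spd"], kinds))


class TestKirkwood:
    def test_closed_form_root(self):
        """Bracketed root matches the quadratic solution of the relation."""
        y = kf_rhs(33.0, 0.0473, 1.0, 300.0)
        closed = ((1.0 + 9.0 * y) + math.sqrt((1.0 + 9.0 * y) ** 2 + 8.0)) / 4.0
        assert epsilon_from_gk(33.0, 0.0473, 1.0, 300.0) == pytest.approx(closed, rel=1e-9)

    def test_zero_dipole_gives_vacuum(self):
        assert epsilon_from_gk(33.0, 0.0, 1.0) == 1.0

    def test_monotone_in_gk(self):
        eps = [epsilon_from_gk(33.0, 0.0473, g) for g in (0.5, 1.0, 2.0)]
        assert eps[0] < eps[1] < eps[2]

    def test_uncorrelated_dipoles_gk_near_one(self, hex_lattice):
        p = da.WaterProfileParams(pair_axis=(0, 1), n_water=600,
                                  eta1_surface=0.0, decay_length=0.2,
                                  n_frames=10, seed=6)
        traj = da.gen_water_between_pair(p, hex_lattice)
        gk = kirkwood_gk(traj, probe_radius=0.4)
        assert gk == pytest.approx(1.0, abs=0.1)

    def test_no_waters_raises(self, frozen_array):
        with pytest.raises(DomainError):
            da.kirkwood_local_epsilon(frozen_array, 0.5)


class TestOccupancyResidence:
    def traj_with_path(self, inside_mask, dt=1.0):
        """One particle stepping in/out of a cutoff sphere at the origin."""
        pos = [np.array([[0.0, 0.0, 0.0] if m else [5.0, 5.0, 0.0]])
               for m in inside_mask]
        n = 1
        top = Topology(ids=np.arange(n), kinds=np.full(n, "na", dtype=object),
                       mol_ids=np.arange(n), charges=np.ones(n))
        frames = [Frame(time=t * dt, box=np.array([10.0, 10.0, 3.4]), pos=p)
                  for t, p in enumerate(pos)]
        return Trajectory(topology=top, frames=frames)

    def test_single_interval_duration(self):
        traj = self.traj_with_path([0, 1, 1, 1, 1, 1, 1, 1, 0, 0])
        res = da.occupancy_residence(traj, np.zeros((1, 3)), cutoff=1.0)
        assert res.mean_residence_ps == pytest.approx(7.0)
        assert res.n_intervals == 1

    def test_gap_merging(self):
        traj = self.traj_with_path([1, 1, 0, 1, 1, 0, 0])
        r0 = da.occupancy_residence(traj, np.zeros((1, 3)), 1.0, gap_tolerance=0)
        r1 = da.occupancy_residence(traj, np.zeros((1, 3)), 1.0, gap_tolerance=1)
        assert r0.n_intervals == 2
        assert r1.n_intervals == 1
        assert r1.mean_residence_ps == pytest.approx(5.0)
        assert set(r1.residence_by_gap) == {0, 1}

    def test_static_occupancy_is_instantaneous_count(self):
        traj = self.traj_with_path([1, 1, 1])
        res = da.occupancy_residence(traj, np.zeros((1, 3)), cutoff=1.0)
        assert res.mean_occupancy == pytest.approx(1.0)

    def test_single_frame_degenerate(self):
        traj = self.traj_with_path([1])
        with pytest.raises(DegenerateInputError):
            da.occupancy_residence(traj, np.zeros((1, 3)), 1.0)
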