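import math

import numpy as np
import pytest

import dnarray as da
from dnarray.errors import (ConsistencyError, DegenerateInputError, DomainError,
                            NoCrossingError)
from dnarray.io import Frame, Trajectory
from dnarray.order import OrderSeriesPoint, discard_equilibration


def shifted_copy(traj, shift_xy):
    """Rigid translation of every frame (same shift all frames)."""
    frames = [Frame(time=f.time, box=f.box, pos=f.pos + np.array([*shift_xy, 0.0]))
              for f in traj.frames]
    return Trajectory(topology=traj.topology, frames=frames, z_period=traj.z_period)


class TestSigmaR:
    def test_gaussian_noise_oracle(self, noisy_array, hex_lattice):
        """2D isotropic Gaussian noise sigma gives radial RMS sigma*sqrt(2).

        Oracle: for x,y ~ N(0, s^2), E[x^2 + y^2] = 2 s^2 exactly; the
        Monte-Carlo estimate at 16 molecules x 2000 frames has a relative
        standard error below 0.5%, so a 3-s.e. band is ~1%.
        """
        sr = da.sigma_r(noisy_array, hex_lattice)
        expected = 0.05 * math.sqrt(2.0)
        n_samp = 16 * len(noisy_array)
        se = expected / math.sqrt(2.0 * n_samp)
        assert abs(sr - expected) < 3.0 * se

    def test_uniform_translation_counts_fully(self, frozen_array, hex_lattice):
        """A rigid array translation each frame is NOT removed by default."""
        rng = np.random.default_rng(0)
        shifts = rng.normal(0, 0.1, size=(len(frozen_array), 2))
        frames = [Frame(time=f.time, box=f.box,
                        pos=f.pos + np.array([*shifts[t], 0.0]))
                  for t, f in enumerate(frozen_array.frames)]
        traj = Trajectory(topology=frozen_array.topology, frames=frames,
                          z_period=frozen_array.z_period)
        dev = shifts - shifts.mean(axis=0)
        expected = math.sqrt(np.mean(np.sum(dev ** 2, axis=1))) / hex_lattice.a
        assert da.sigma_r(traj, hex_lattice) == pytest.approx(expected, rel=1e-9)
        # and the optional drift removal takes it back to zero
        assert da.sigma_r(traj, hex_lattice, remove_drift=True) == pytest.approx(0.0, abs=1e-12)

    def test_single_frame_is_degenerate(self, frozen_array, hex_lattice):
        one = Trajectory(topology=frozen_array.topology,
                         frames=frozen_array.frames[:1])
        with pytest.raises(DegenerateInputError):
            da.sigma_r(one, hex_lattice)

    def test_invariant_under_global_translation(self, noisy_array, hex_lattice):
        moved = shifted_copy(noisy_array, (3.7, -1.2))
        assert da.sigma_r(moved, hex_lattice) == pytest.approx(
            da.sigma_r(noisy_array, hex_lattice), rel=1e-12)


class TestDeltaPhi:
    def test_identical_molecules_give_zero(self, frozen_array):
        # molecules 0 and 4 share the same generation pattern up to the
        # preferred offset; use the same molecule against itself
        dp = da.delta_phi_pair(frozen_array, 0, 0)
        np.testing.assert_allclose(dp, 0.0, atol=1e-12)

    def test_screw_displacement_cancels(self, hex_lattice):
        """A screwed duplicate (dz with matching helical rotation) gives 0."""
        p = da.ArrayFluctuationParams(
            lattice=hex_lattice, sigma_pos=0.0, sigma_phi=0.0,
            preferred_delta_phi=0.0, screw_coupling=True, n_frames=10, seed=21)
        traj = da.gen_array(p)
        for i, j in [(0, 1), (5, 6), (9, 10)]:
            np.testing.assert_allclose(da.delta_phi_pair(traj, i, j), 0.0,
                                       atol=1e-9)

    def test_rigid_rotation_recovered(self, hex_lattice):
        delta = 0.37
        p = da.ArrayFluctuationParams(
            lattice=hex_lattice, sigma_pos=0.0, sigma_phi=0.0,
            preferred_delta_phi=delta, screw_coupling=False, n_frames=2, seed=0)
        traj = da.gen_array(p)
        # neighbors in a row differ by exactly delta in molecular azimuth
        dp = da.delta_phi_pair(traj, 1, 0)
        np.testing.assert_allclose(dp, delta, atol=1e-12)

    def test_mismatched_bp_counts_rejected(self, hex_lattice):
        p1 = da.ArrayFluctuationParams(lattice=hex_lattice, sigma_pos=0.0,
                                       sigma_phi=0.0, preferred_delta_phi=0.0,
                                       n_frames=1, n_bp=10, seed=0)
        traj = da.gen_array(p1)
        # corrupt: drop one base pair of molecule 1 from the topology
        top = traj.topology
        keep = ~((top.mol_ids == 1) & (top.bps == 9))
        import dataclasses
        top2 = dataclasses.replace(
            top, ids=top.ids[keep], kinds=top.kinds[keep],
            mol_ids=top.mol_ids[keep], charges=top.charges[keep],
            roles=top.roles[keep], bps=top.bps[keep])
        frames = [Frame(time=f.time, box=f.box, pos=f.pos[keep])
                  for f in traj.frames]
        bad = Trajectory(topology=top2, frames=frames)
        with pytest.raises(ConsistencyError):
            da.delta_phi_pair(bad, 0, 1)

    def test_wrap_never_exceeds_pi(self, noisy_array):
        dp = da.delta_phi_pair(noisy_array, 0, 1)
        assert np.all(np.abs(dp) <= math.pi + 1e-12)


class TestSigmaPhi:
    def test_independent_gaussian_noise_oracle(self, noisy_array, hex_lattice):
        """Independent molecular azimuth noise sigma gives sqrt(2) sigma / pi."""
        shell = da.first_neighbor_shell(hex_lattice)
        sp = da.sigma_phi(noisy_array, shell)
        expected = math.sqrt(2.0) * 0.1 / math.pi
        se = expected / math.sqrt(2.0 * len(noisy_array))  # per-pair; pairs correlate
        assert abs(sp - expected) < 3.0 * max(se, 0.01 * expected)

    def test_global_rotation_invariance(self, hex_lattice):
        """Rotating every molecule identically each frame changes nothing."""
        p = da.ArrayFluctuationParams(
            lattice=hex_lattice, sigma_pos=0.0, sigma_phi=0.0,
            preferred_delta_phi=0.3, n_frames=50, seed=2)
        traj = da.gen_array(p)
        shell = da.first_neighbor_shell(hex_lattice)
        assert da.sigma_phi(traj, shell) == pytest.approx(0.0, abs=1e-12)

    def test_empty_shell_rejected(self, noisy_array):
        from dnarray.lattice import NeighborShell
        with pytest.raises(DomainError):
            da.sigma_phi(noisy_array, NeighborShell([], 1.0, 0))

    def test_monotone_in_noise_amplitude(self, hex_lattice):
        shell = da.first_neighbor_shell(hex_lattice)
        values = []
        for amp in (0.05, 0.15, 0.45):
            p = da.ArrayFluctuationParams(
                lattice=hex_lattice, sigma_pos=amp * hex_lattice.a / 3,
                sigma_phi=amp, preferred_delta_phi=2 * math.pi / 3,
                n_frames=400, seed=13)
            traj = da.gen_array(p)
            values.append((da.sigma_r(traj, hex_lattice),
                           da.sigma_phi(traj, shell)))
        srs, sps = zip(*values)
        assert srs[0] < srs[1] < srs[2]
        assert sps[0] < sps[1] < sps[2]


class TestLindemann:
    @pytest.mark.parametrize("value,expected", [
        (0.05, "ordered"), (0.15, "disordered"), (0.1, "disordered")])
    def test_classification_boundary(self, value, expected):
        assert da.lindemann_classify(value) == expected

    def test_linear_bracket_interpolation(self):
        series = [
            OrderSeriesPoint(600.0, 2.5, 0.15, 0.2, 100),
            OrderSeriesPoint(800.0, 2.2, 0.05, 0.08, 100),
        ]
        assert da.transition_density(series, "positional") == pytest.approx(700.0)

    def test_no_crossing_reports_side(self):
        series = [
            OrderSeriesPoint(600.0, 2.5, 0.02, 0.01, 100),
            OrderSeriesPoint(800.0, 2.2, 0.01, 0.005, 100),
        ]
        with pytest.raises(NoCrossingError) as exc:
            da.transition_density(series, "positional")
        assert exc.value.side == "below"


def test_discard_equilibration_slices_frames(noisy_array):
    tr = discard_equilibration(noisy_array, 0.25)
    assert len(tr) == 1500 and tr.frames[0] is noisy_array.frames[500]
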