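import math

import numpy as np
import pytest

from dnarray.adress import (FluidConfig, ResolutionGeometry, TDForceTable,
                            adress_force, adress_pair_forces, calibrate_td_force,
                            demo_setup, gaussian_core_force, resolution_weight,
                            wca_force)
from dnarray.errors import DomainError
from dnarray.geometry import RoundedRhombus


@pytest.fixture(scope="module")
def geometry():
    ang = math.radians(60.0)
    region = RoundedRhombus(center=np.array([6.0, 6.0]), u=np.array([1.0, 0.0]),
                            v=np.array([math.cos(ang), math.sin(ang)]),
                            half_u=2.2, half_v=2.2, rounding=0.3)
    return ResolutionGeometry(region=region, hybrid_width=1.8)


class TestResolutionWeight:
    def test_limits_and_midpoint(self, geometry):
        center = geometry.region.center
        assert resolution_weight(center, geometry) == 1.0
        far = center + np.array([50.0, 0.0])
        assert resolution_weight(far, geometry) == 0.0
        # point at the hybrid midline along the +x normal direction
        s_mid = geometry.hybrid_width / 2.0
        edge_x = geometry.region.half_v * geometry.region._sin + geometry.region.rounding
        p = center + np.array([0.0, edge_x + s_mid])
        assert resolution_weight(p, geometry) == pytest.approx(0.5, abs=1e-9)

    def test_continuity_modulus(self, geometry):
        """|w(p) - w(p + delta)| -> 0 with |delta| along the outward normal."""
        base = geometry.region.center + np.array([0.0, 3.2])
        for h in (1e-3, 1e-5):
            w1 = resolution_weight(base, geometry)
            w2 = resolution_weight(base + np.array([0.0, h]), geometry)
            assert abs(w1 - w2) < 3.0 * h  # slope bounded by pi/(2W) < 1

    def test_monotone_along_normal(self, geometry):
        c = geometry.region.center
        ts = np.linspace(0.0, 6.0, 60)
        w = resolution_weight(c + np.outer(ts, [0.0, 1.0]), geometry)
        assert np.all(np.diff(w) <= 1e-12)


class TestAdressForce:
    def random_state(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(2, 10, size=(n, 2))
        w = rng.uniform(0, 1, size=n)
        iu, ju = np.triu_indices(n, k=1)
        pairs = np.column_stack([iu, ju])
        return pos, w, pairs

    def test_identical_potentials_interpolation_identity(self):
        """With F_ex = F_cg and no TD force the total equals F_ex exactly."""
        pos, w, pairs = self.random_state()
        fex, _ = wca_force(eps=2.0, sigma=1.5)
        f_mixed = adress_pair_forces(pos, w, fex, fex, pairs)
        f_pure = adress_pair_forces(pos, np.ones(len(pos)), fex, fex, pairs)
        np.testing.assert_allclose(f_mixed, f_pure, atol=1e-12)

    @pytest.mark.parametrize("wval,which", [(1.0, "ex"), (0.0, "cg")])
    def test_pure_region_limits(self, wval, which):
        pos, _, pairs = self.random_state(10, seed=3)
        fex, _ = wca_force(eps=2.0, sigma=1.2)
        fcg, _ = gaussian_core_force(eps=1.0, sigma=2.0, cutoff=20.0)
        w = np.full(len(pos), wval)
        mixed = adress_pair_forces(pos, w, fex, fcg, pairs)
        pure = adress_pair_forces(pos, np.ones(len(pos)), fex if which == "ex" else fcg,
                                  fex if which == "ex" else fcg, pairs)
        np.testing.assert_allclose(mixed, pure, atol=1e-12)

    def test_pairwise_momentum_conservation(self):
        """The pair part of the interpolation sums to zero force exactly."""
        pos, w, pairs = self.random_state(30, seed=8)
        fex, _ = wca_force(eps=2.0, sigma=1.5)
        fcg, _ = gaussian_core_force(eps=1.5, sigma=2.0, cutoff=30.0)
        f = adress_pair_forces(pos, w, fex, fcg, pairs)
        # antisymmetric per pair; the total vanishes to accumulation roundoff
        scale = np.abs(f).max()
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-12 * max(scale, 1.0))

    def test_td_term_applied_along_normal(self, geometry):
        table = TDForceTable.zero(geometry.hybrid_width, 10)
        table.forces[:] = 2.0
        p = geometry.region.center + np.array([[0.0, 3.2]])
        fex, _ = wca_force()
        f = adress_force(p, np.array([0.5]), fex, fex, table, geometry,
                         np.empty((0, 2), dtype=int))
        np.testing.assert_allclose(f[0], [0.0, 2.0], atol=1e-9)


class TestCalibration:
    def test_identical_potentials_converge_immediately(self, geometry):
        """No chemical-potential mismatch: flat at iteration 0, zero table."""
        config = FluidConfig()  # f_ex == f_cg == WCA
        table = calibrate_td_force(config, geometry, max_iters=3, tol=0.05,
                                   seed=1, steps_per_iter=4000,
                                   equilibration_steps=1500)
        assert table.converged
        assert table.iterations == 0
        np.testing.assert_array_equal(table.forces, 0.0)

    def test_zero_gain_is_noop(self, geometry):
        config, geom = demo_setup(mismatched=True)
        with pytest.warns(UserWarning, match="did not reach"):
            table = calibrate_td_force(config, geom, max_iters=2, tol=1e-6,
                                       seed=1, gain=0.0, steps_per_iter=300,
                                       equilibration_steps=100)
        np.testing.assert_array_equal(table.forces, 0.0)
        assert not table.converged

    def test_nonconvergence_warns_not_raises(self, geometry):
        config, geom = demo_setup(mismatched=True)
        with pytest.warns(UserWarning, match="did not reach"):
            table = calibrate_td_force(config, geom, max_iters=0, tol=1e-9,
                                       seed=1, steps_per_iter=300,
                                       equilibration_steps=100)
        assert np.isfinite(table.convergence_metric)


def test_hybrid_width_must_be_positive(geometry):
    with pytest.raises(DomainError):
        ResolutionGeometry(region=geometry.region, hybrid_width=0.0)
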