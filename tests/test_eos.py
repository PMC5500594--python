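import numpy as np
import pytest

import dnarray as da
from dnarray.eos import EoSTable, fit_exponential, osmotic_pressure
from dnarray.errors import DegenerateInputError, FitError
from dnarray.order import OrderSeriesPoint
from dnarray.simulate import WallForceTrace


def trace_of(forces, area=10.0):
    return WallForceTrace(forces=np.asarray(forces, float),
                          membrane_area=area, cross_section=5.0)


class TestOsmoticPressure:
    def test_constant_force_exact_no_spread(self):
        p, sd = osmotic_pressure(trace_of(np.full(100, 30.0), area=10.0))
        assert p == pytest.approx(3.0)
        assert sd == 0.0

    def test_zero_particles_zero_pressure(self):
        p, sd = osmotic_pressure(trace_of(np.zeros(50)))
        assert p == 0.0 and sd == 0.0

    def test_short_trace_degenerate(self):
        with pytest.raises(DegenerateInputError):
            osmotic_pressure(trace_of(np.ones(4)))

    def test_equilibration_discarded(self):
        forces = np.concatenate([np.full(10, 1000.0), np.full(90, 10.0)])
        p, _ = osmotic_pressure(trace_of(forces, area=10.0))
        assert p == pytest.approx(1.0)

    def test_subsampling_within_two_sd(self):
        rng = np.random.default_rng(5)
        forces = 50.0 + rng.normal(0, 5, size=2000)
        p0, sd0 = osmotic_pressure(trace_of(forces))
        for stride in (2, 3, 5):
            p, sd = osmotic_pressure(trace_of(forces[::stride]))
            assert abs(p - p0) < 2.0 * (sd0 ** 2 + sd ** 2) ** 0.5 + 1e-12


class TestExponentialFit:
    def synthetic_table(self, pi0=10.0, lam=0.3, n=5, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        d = np.linspace(2.0, 3.6, n)
        p = pi0 * np.exp(-d / lam)
        p = p * np.exp(rng.normal(0.0, noise, size=n))
        return EoSTable(spacing=d,
                        concentration=da.spacing_to_concentration(d[0]) * (d[0] / d) ** 2,
                        pressure=p, pressure_sd=noise * p)

    def test_noiseless_exact_recovery(self):
        fit = fit_exponential(self.synthetic_table(), vs="spacing")
        assert fit.prefactor == pytest.approx(10.0, rel=1e-6)
        assert fit.scale == pytest.approx(0.3, rel=1e-6)

    def test_parameter_bias_under_noise(self):
        """5% multiplicative noise, 8 points, 100 seeds: bias < 2%."""
        lams, pis = [], []
        for seed in range(100):
            t = self.synthetic_table(n=8, noise=0.05, seed=seed)
            fit = fit_exponential(t, vs="spacing")
            lams.append(fit.scale)
            pis.append(fit.prefactor)
        assert abs(np.mean(lams) - 0.3) / 0.3 < 0.02
        assert abs(np.mean(pis) - 10.0) / 10.0 < 0.02

    def test_two_points_is_fit_error(self):
        t = self.synthetic_table(n=2)
        with pytest.raises(FitError):
            fit_exponential(t, vs="spacing")

    def test_nonpositive_rows_excluded_with_warning(self):
        t = self.synthetic_table(n=6)
        t.pressure[0] = -1.0
        with pytest.warns(UserWarning, match="non-positive"):
            fit = fit_exponential(t, vs="spacing")
        assert fit.scale == pytest.approx(0.3, rel=1e-6)

    def test_concentration_abscissa_supported(self):
        c = np.array([300.0, 500.0, 700.0, 900.0])
        p = 0.01 * np.exp(c / 250.0)
        t = EoSTable(spacing=da.concentration_to_spacing(c[0]) * np.sqrt(c[0] / c),
                     concentration=c, pressure=p, pressure_sd=np.zeros(4))
        fit = fit_exponential(t, vs="concentration")
        assert fit.scale == pytest.approx(250.0, rel=1e-6)
        assert fit.predict(600.0) == pytest.approx(0.01 * np.exp(600.0 / 250.0), rel=1e-6)


class TestPhaseAssembly:
    def series(self):
        # sigma values grow toward low concentration; rotational order is
        # lost at higher concentration than positional order
        return [
            OrderSeriesPoint(300.0, 3.4, 0.30, 0.50, 100),
            OrderSeriesPoint(500.0, 2.9, 0.15, 0.30, 100),
            OrderSeriesPoint(700.0, 2.4, 0.05, 0.15, 100),
            OrderSeriesPoint(900.0, 2.1, 0.02, 0.05, 100),
        ]

    def eos(self):
        c = np.array([300.0, 500.0, 700.0, 900.0])
        return EoSTable(spacing=np.array([3.4, 2.9, 2.4, 2.1]),
                        concentration=c,
                        pressure=0.05 * np.exp(c / 300.0),
                        pressure_sd=np.zeros(4))

    def test_crossings_and_band_ordering(self):
        report = da.assemble_phase_diagram(self.series(), self.eos())
        assert report.positional.concentration == pytest.approx(600.0)
        assert report.rotational.concentration == pytest.approx(800.0)
        assert report.rotational.concentration > report.positional.concentration
        bands = list(report.bands["band"])
        assert bands[0].startswith("disordered")
        assert bands[1].startswith("disordered")   # 500 < positional crossing
        assert bands[2].startswith("hex")
        assert bands[3].startswith("orto")

    def test_pressure_from_fitted_eos(self):
        report = da.assemble_phase_diagram(self.series(), self.eos())
        fit = fit_exponential(self.eos(), vs="concentration")
        assert report.positional.pressure == pytest.approx(
            float(fit.predict(600.0)), rel=1e-9)

    def test_thresholds_above_all_sigmas_single_phase(self):
        report = da.assemble_phase_diagram(self.series(), self.eos(), threshold=0.9)
        assert report.positional is None and report.rotational is None
        assert len(set(report.bands["band"])) == 1

    def test_report_deterministic(self):
        a = da.assemble_phase_diagram(self.series(), self.eos())
        b = da.assemble_phase_diagram(self.series(), self.eos())
        assert a.positional.concentration == b.positional.concentration
        assert a.bands.equals(b.bands)
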