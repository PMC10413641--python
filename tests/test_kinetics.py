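"""Adsorption kinetics: band areas, biexponential fits, NR/FTIR agreement."""

import numpy as np
import pytest

from nrpore.kinetics import (
    KineticTrace,
    amide_band_area,
    compare_traces,
    fit_biexponential,
)
from nrpore.synthetic import (
    ftir_schedule,
    generate_kinetic_trace,
    nr_schedule,
)


class TestAmideBandArea:
    WN = np.linspace(1500.0, 1800.0, 600)

    def test_zero_spectrum(self):
        assert amide_band_area(self.WN, np.zeros_like(self.WN)) == 0.0

    def test_gaussian_band_analytic_area(self):
        """Band fully inside the window: trapezoid matches the closed form."""
        area, center, width = 3.2, 1650.0, 10.0
        ab = area / np.sqrt(2 * np.pi * width**2) * np.exp(
            -0.5 * ((self.WN - center) / width) ** 2
        )
        got = amide_band_area(self.WN, ab)
        assert got == pytest.approx(area, rel=1e-3)

    def test_constant_offset_removed_by_baseline(self):
        ab = 0.01 * np.exp(-0.5 * ((self.WN - 1650.0) / 10.0) ** 2)
        a0 = amide_band_area(self.WN, ab)
        a1 = amide_band_area(self.WN, ab + 0.7)
        assert a1 == pytest.approx(a0, rel=1e-9)

    def test_descending_wavenumber_storage(self):
        ab = 0.01 * np.exp(-0.5 * ((self.WN - 1650.0) / 10.0) ** 2)
        a_fwd = amide_band_area(self.WN, ab)
        a_rev = amide_band_area(self.WN[::-1], ab[::-1])
        assert a_rev == pytest.approx(a_fwd, rel=1e-9)

    def test_window_outside_spectrum_raises(self):
        with pytest.raises(ValueError):
            amide_band_area(self.WN, np.zeros_like(self.WN), window=(1400, 1700))


class TestBiexponentialFit:
    def test_noiseless_exact_recovery(self):
        t = ftir_schedule(600.0)
        tr = generate_kinetic_trace(0.6, 10.0, 0.4, 175.0, t, noise_frac=0.0, seed=0)
        fit = fit_biexponential(tr, seed=0)
        assert fit.a_fast == pytest.approx(0.6, rel=1e-3)
        assert fit.tau_fast == pytest.approx(10.0, rel=1e-3)
        assert fit.a_slow == pytest.approx(0.4, rel=1e-3)
        assert fit.tau_slow == pytest.approx(175.0, rel=1e-3)
        assert fit.tau_fast < fit.tau_slow

    def test_noisy_recovery_within_reported_uncertainties(self):
        """2% noise on the FTIR schedule: fast 10 +/- 2 min, slow 175 +/- 15."""
        t = ftir_schedule(600.0)
        tr = generate_kinetic_trace(0.6, 10.0, 0.4, 175.0, t, noise_frac=0.02, seed=42)
        fit = fit_biexponential(tr, seed=1)
        assert abs(fit.tau_fast - 10.0) < 2.0
        assert abs(fit.tau_slow - 175.0) < 15.0
        assert not fit.degenerate

    def test_single_exponential_data_flagged_degenerate(self):
        t = ftir_schedule(600.0)
        tr = generate_kinetic_trace(0.0, 1.0, 1.0, 100.0, t, noise_frac=0.0, seed=0)
        fit = fit_biexponential(tr, seed=0)
        assert fit.degenerate

    def test_residuals_mean_zero_on_well_specified_data(self):
        t = ftir_schedule(400.0)
        tr = generate_kinetic_trace(0.6, 10.0, 0.4, 175.0, t, noise_frac=0.03, seed=9)
        fit = fit_biexponential(tr, seed=9)
        model = (
            fit.baseline
            + fit.a_fast * (1 - np.exp(-tr.t / fit.tau_fast))
            + fit.a_slow * (1 - np.exp(-tr.t / fit.tau_slow))
        )
        resid = (tr.y - model) / tr.dy
        assert abs(resid.mean()) < 3.0 / np.sqrt(len(tr))

    def test_too_few_points_raises(self):
        tr = KineticTrace(t=[1, 2, 3], y=[0.1, 0.2, 0.3], dy=[0.01] * 3)
        with pytest.raises(ValueError):
            fit_biexponential(tr)

    def test_coarser_sampling_inflates_tau_uncertainty(self):
        """Widening the NR bins monotonically degrades the slow-constant
        precision in simulation."""
        widths = [20.0, 50.0, 100.0]
        errs = []
        for w in widths:
            mids, spans = nr_schedule(600.0, w)
            tr = generate_kinetic_trace(
                0.0, 1.0, 1.0, 110.0, mids, noise_frac=0.05, seed=3, t_window=spans
            )
            fit = fit_biexponential(tr, seed=3, n_exp=1)
            errs.append(fit.errors["tau_slow"])
        assert errs[0] < errs[-1]


class TestCompareTraces:
    def test_identical_traces(self):
        t = ftir_schedule(500.0)
        tr = generate_kinetic_trace(0.6, 10.0, 0.4, 175.0, t, noise_frac=0.01, seed=5)
        rep = compare_traces(tr, tr, seed=0)
        assert rep["correlation"] == pytest.approx(1.0, abs=1e-9)
        assert rep["tau_slow_ratio"] == pytest.approx(1.0, rel=1e-6)

    def test_same_kinetics_different_sampling_agree(self):
        """FTIR (80 s) and NR (50 min bins) sampling of one biexponential
        process overlay with correlation > 0.95."""
        ftir = generate_kinetic_trace(
            0.6, 10.0, 0.4, 175.0, ftir_schedule(600.0), noise_frac=0.02, seed=6
        )
        mids, spans = nr_schedule(600.0, 50.0)
        nr = generate_kinetic_trace(
            0.6, 10.0, 0.4, 175.0, mids, noise_frac=0.05, seed=7, t_window=spans
        )
        rep = compare_traces(nr, ftir, seed=0)
        assert rep["correlation"] > 0.95

    def test_nr_sampled_slow_constant_near_110(self):
        """Slow-phase constant recovered from the coarse NR schedule when
        generated at 110 min (the reflectometry-determined value)."""
        mids, spans = nr_schedule(600.0, 50.0)
        nr = generate_kinetic_trace(
            0.0, 1.0, 1.0, 110.0, mids, noise_frac=0.05, seed=6, t_window=spans
        )
        fit = fit_biexponential(nr, seed=6, n_exp=1)
        assert abs(fit.tau_slow - 110.0) < 30.0

    def test_disjoint_time_ranges_raise(self):
        a = KineticTrace(t=np.arange(1.0, 10.0), y=np.ones(9), dy=np.ones(9))
        b = KineticTrace(t=np.arange(20.0, 30.0), y=np.ones(10), dy=np.ones(10))
        with pytest.raises(ValueError):
            compare_traces(a, b)
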