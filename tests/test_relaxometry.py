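"""Multiexponential CPMG fitting and quasi-continuous T2 inversion."""

import math

import numpy as np
import pytest

from caseoscan import synthetic
from caseoscan.relaxometry import (
    CpmgDecay,
    ProtonPopulation,
    T2Spectrum,
    decay_model,
    decimate_log,
    fit_multiexponential,
    invert_t2_spectrum,
    population_areas,
)
from caseoscan.synthetic import NDC_POPULATIONS

NDC_T2 = [1.55, 10.78, 51.10, 170.79]
NDC_PCT = [5.44, 55.06, 23.58, 15.92]


class TestForwardModel:
    def test_single_population_limits(self):
        pops = [ProtonPopulation("A", 100.0, 100.0)]
        assert decay_model(pops, np.array([0.0]), s0=7.0)[0] == pytest.approx(7.0)
        assert decay_model(pops, np.array([100.0]), s0=7.0)[0] == pytest.approx(7.0 / math.e)

    def test_four_population_sum_matches_direct_evaluation(self):
        # oracle: sum the four exponentials by hand at t = 10.78 ms
        t = 10.78
        expected = 100.0 * sum(
            (p / 100.0) * math.exp(-t / t2) for p, t2 in zip(NDC_PCT, NDC_T2)
        )
        got = decay_model(NDC_POPULATIONS, np.array([t]))[0]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_t2_rejected(self):
        with pytest.raises(ValueError):
            decay_model([(100.0, -5.0)], np.array([1.0]))

    def test_echo_time_convention(self):
        d = CpmgDecay.from_train(np.ones(5), tau_us=80.0)
        assert d.echo_times == pytest.approx(0.16 * np.arange(1, 6))


class TestDecimation:
    def test_short_series_untouched(self):
        t = np.linspace(1, 10, 50)
        y = np.exp(-t)
        td, yd, c = decimate_log(t, y, max_points=100)
        assert np.array_equal(td, t) and np.array_equal(yd, y)

    def test_counts_conserve_points(self):
        t = 0.16 * np.arange(1, 30001)
        td, _, c = decimate_log(t, np.ones_like(t), max_points=2000)
        assert c.sum() == 30000
        assert td.size <= 2000
        assert np.all(np.diff(td) > 0)


class TestMultiexponentialFit:
    def test_noiseless_single_exponential(self):
        decay, _ = synthetic.make_cpmg_decay([(100.0, 100.0)], n_points=5000, snr=None)
        fit = fit_multiexponential(decay, n_components=1, seed=0)
        assert fit.populations[0].t2_ms == pytest.approx(100.0, abs=0.1)
        assert fit.populations[0].abundance_pct == pytest.approx(100.0)
        assert fit.converged

    @pytest.mark.parametrize(
        "pairs",
        [
            [(100.0, 40.0)],
            [(60.0, 10.0), (40.0, 100.0)],
            [(30.0, 2.0), (40.0, 20.0), (30.0, 200.0)],
            list(zip(NDC_PCT, NDC_T2)),
        ],
    )
    def test_forward_fit_roundtrip_noiseless(self, pairs):
        # T2s separated >= ~3x: every parameter back within 0.5 %
        decay, _ = synthetic.make_cpmg_decay(pairs, snr=None)
        fit = fit_multiexponential(decay, n_components=len(pairs), seed=0)
        for pop, (pct, t2) in zip(fit.populations, pairs):
            assert pop.t2_ms == pytest.approx(t2, rel=0.005)
            assert pop.abundance_pct == pytest.approx(pct, rel=0.005)

    def test_abundances_sum_to_100(self, ndc_noisy_decay):
        decay, _ = ndc_noisy_decay
        fit = fit_multiexponential(decay, n_components=4, seed=0)
        assert fit.abundances().sum() == pytest.approx(100.0, abs=1e-6)
        assert [p.label for p in fit.populations] == ["A", "B", "C", "D"]
        assert np.all(np.diff(fit.t2s()) > 0)

    def test_slowest_population_recovered(self, ndc_noisy_decay):
        decay, truth = ndc_noisy_decay
        fit = fit_multiexponential(decay, n_components=4, seed=0)
        assert fit.populations[3].t2_ms == pytest.approx(170.79, rel=0.03)

    def test_overparameterised_fit_degenerates_gracefully(self):
        pairs = [(60.0, 10.0), (40.0, 100.0)]
        decay, _ = synthetic.make_cpmg_decay(pairs, snr=1000.0, seed=1)
        fit4 = fit_multiexponential(decay, n_components=4, seed=1)
        fit2 = fit_multiexponential(decay, n_components=2, seed=1)
        assert len(fit4.degenerate) >= 2 or fit4.residual_norm <= fit2.residual_norm * (1 + 1e-9)

    def test_residual_nonincreasing_in_components(self):
        decay, _ = synthetic.make_cpmg_decay(snr=1000.0, seed=3)
        res = [
            fit_multiexponential(decay, n_components=n, seed=3).residual_norm
            for n in (1, 2, 3, 4)
        ]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(res, res[1:]))

    def test_too_short_decay_rejected(self):
        decay = CpmgDecay.from_train(np.exp(-np.arange(1, 21) / 5.0))
        with pytest.raises(ValueError):
            fit_multiexponential(decay, n_components=4)

    def test_monte_carlo_population_b(self):
        # 20 noisy realisations: median T2B error < 2 %, abundance B < 2 pts
        t2b_err, pct_err = [], []
        for seed in range(20):
            decay, _ = synthetic.make_cpmg_decay(snr=1000.0, seed=seed)
            fit = fit_multiexponential(decay, n_components=4, seed=seed)
            t2b_err.append(abs(fit.populations[1].t2_ms - 10.78) / 10.78)
            pct_err.append(abs(fit.populations[1].abundance_pct - 55.06))
        assert np.median(t2b_err) < 0.02
        assert np.median(pct_err) < 2.0


class TestSpectrumInversion:
    def test_single_exponential_unimodal(self):
        decay, _ = synthetic.make_cpmg_decay([(100.0, 50.0)], n_points=5000, snr=None)
        spec = invert_t2_spectrum(decay)
        modes = spec.modes_ms()
        assert modes.size == 1
        step = spec.t2_grid[1] / spec.t2_grid[0]
        assert modes[0] / 50.0 < step and 50.0 / modes[0] < step

    def test_four_populations_resolved(self, ndc_noisy_decay):
        decay, _ = ndc_noisy_decay
        spec = invert_t2_spectrum(decay)
        modes = spec.modes_ms()
        assert modes.size == 4
        for mode, t2 in zip(modes, NDC_T2):
            assert mode == pytest.approx(t2, rel=0.15)

    def test_nonnegative_and_area_conserving(self, ndc_noisy_decay):
        decay, truth = ndc_noisy_decay
        spec = invert_t2_spectrum(decay)
        assert np.all(spec.density >= 0)
        assert spec.total_amplitude() == pytest.approx(truth.parameters["s0"], rel=0.02)

    def test_heavy_smoothing_flattens_but_conserves(self, ndc_noisy_decay):
        decay, truth = ndc_noisy_decay
        curvatures, totals = [], []
        for lam in (0.1, 3.0, 30.0):
            spec = invert_t2_spectrum(decay, smoothing_weight=lam)
            curvatures.append(float(np.sum(np.diff(spec.density, 2) ** 2)))
            totals.append(spec.total_amplitude())
        assert curvatures[0] > curvatures[1] > curvatures[2]
        for total in totals:
            assert total == pytest.approx(truth.parameters["s0"], rel=0.02)

    def test_all_zero_signal_rejected(self):
        decay = CpmgDecay.from_train(np.zeros(100))
        with pytest.raises(ValueError):
            invert_t2_spectrum(decay)

    def test_coarse_grid_warns_in_metadata(self, ndc_noisy_decay):
        decay, _ = ndc_noisy_decay
        spec = invert_t2_spectrum(decay, t2_grid=np.geomspace(0.1, 3000.0, 12))
        assert any("decade" in w for w in spec.warnings)


class TestPopulationAreas:
    def test_whole_grid_is_everything(self):
        decay, _ = synthetic.make_cpmg_decay([(100.0, 50.0)], n_points=5000, snr=None)
        spec = invert_t2_spectrum(decay)
        assert population_areas(spec, [])[0] == pytest.approx(100.0)

    def test_ndc_abundances_within_2_points(self, ndc_noisy_decay):
        decay, _ = ndc_noisy_decay
        spec = invert_t2_spectrum(decay)
        areas = population_areas(spec)  # valley cut points
        assert len(areas) == 4
        assert sum(areas) == pytest.approx(100.0, abs=1e-9)
        for got, expected in zip(areas, NDC_PCT):
            assert got == pytest.approx(expected, abs=2.0)

    def test_empty_interval_near_zero(self):
        grid = np.geomspace(0.1, 3000.0, 200)
        density = np.exp(-((np.log(grid) - np.log(50.0)) ** 2))
        spec = T2Spectrum(t2_grid=grid, density=density, smoothing_weight=0.0)
        low, mid, high = population_areas(spec, [1.0, 5.0])
        assert mid == pytest.approx(0.0, abs=0.5)

    def test_boundary_outside_grid_rejected(self):
        grid = np.geomspace(0.1, 3000.0, 50)
        spec = T2Spectrum(t2_grid=grid, density=np.ones(50), smoothing_weight=0.0)
        with pytest.raises(ValueError):
            population_areas(spec, [5000.0])
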