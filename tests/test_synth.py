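"""Generator fidelity: simulated tuples and waveforms must carry exactly
the statistics the model prescribes."""

import math

import numpy as np
import pytest
from scipy import stats

from icam.model import ModelParams, conditional_ion_mean, detected_count_mean
from icam.synth import (
    WaveformConfig,
    make_phantom,
    simulate_image,
    simulate_pixel,
    simulate_pixels,
    simulate_waveform,
)

from conftest import C_MU, C_SIGMA


class TestSimulatePixel:
    def test_zero_dose_gives_empty_pixel(self, rng):
        params = ModelParams(dose=0.0, yield_eta=2.0)
        for _ in range(20):
            truth, meas = simulate_pixel(params, rng)
            assert truth.ion_count == 0 and meas.pulse_count == 0
            assert meas.total_voltage == 0.0

    def test_tuple_invariants(self, rng):
        params = ModelParams(dose=10.0, yield_eta=2.0)
        truth, meas = simulate_pixel(params, rng)
        assert truth.total_se == sum(truth.se_counts)
        assert meas.pulse_count == sum(1 for x in truth.se_counts if x >= 1)
        assert meas.total_voltage == pytest.approx(sum(meas.peak_heights))


class TestSimulatePixelsMoments:
    N = 200_000

    def test_detected_count_and_voltage_means(self, rng):
        params = ModelParams(dose=10.0, yield_eta=2.0, c_mu=C_MU, c_sigma=C_SIGMA)
        sim = simulate_pixels(params, self.N, rng)
        mu = detected_count_mean(10.0, 2.0)
        se = sim["m_tilde"].std(ddof=1) / math.sqrt(self.N)
        assert abs(sim["m_tilde"].mean() - mu) < 3 * se
        v_mean = 10.0 * 2.0 * C_MU
        se_v = sim["v"].std(ddof=1) / math.sqrt(self.N)
        assert abs(sim["v"].mean() - v_mean) < 3 * se_v

    def test_total_se_moments(self, rng):
        params = ModelParams(dose=10.0, yield_eta=2.0)
        sim = simulate_pixels(params, self.N, rng)
        y = sim["y"]
        se_mean = y.std(ddof=1) / math.sqrt(self.N)
        assert abs(y.mean() - 20.0) < 3 * se_mean
        var = y.var(ddof=1)
        se_var = var * math.sqrt(2.0 / (self.N - 1))  # approx SE of a variance
        assert abs(var - 60.0) < 3 * se_var * 1.5  # kurtosis margin

    def test_conditional_ion_mean_binned_regression(self, rng):
        lam, eta = 10.0, 2.0
        params = ModelParams(dose=lam, yield_eta=eta)
        sim = simulate_pixels(params, 400_000, rng)
        m, mt = sim["m"], sim["m_tilde"]
        for k in np.unique(mt):
            sel = mt == k
            if sel.sum() < 1000:
                continue
            pred = conditional_ion_mean(int(k), lam, eta)
            se = m[sel].std(ddof=1) / math.sqrt(sel.sum())
            assert abs(m[sel].mean() - pred) < 3 * se

    def test_mse_reduction_factor_exp_minus_eta(self, rng):
        # (M~ + lam e^-eta) predicts M with e^-eta times the MSE of the
        # constant predictor lam
        lam, eta = 10.0, 2.0
        params = ModelParams(dose=lam, yield_eta=eta)
        sim = simulate_pixels(params, 400_000, rng)
        mse_icam = np.mean((sim["m_tilde"] + lam * math.exp(-eta) - sim["m"]) ** 2)
        mse_const = np.mean((lam - sim["m"]) ** 2)
        assert mse_icam / mse_const == pytest.approx(math.exp(-eta), rel=0.02)

    def test_seed_determinism_and_seed_independence(self):
        params = ModelParams(dose=10.0, yield_eta=2.0)
        a = simulate_pixels(params, 5000, np.random.default_rng(7))
        b = simulate_pixels(params, 5000, np.random.default_rng(7))
        np.testing.assert_array_equal(a["v"], b["v"])
        for other_seed in (8, 99, 1234):
            c = simulate_pixels(params, 5000, np.random.default_rng(other_seed))
            _, p = stats.ks_2samp(a["v"], c["v"])
            assert p > 0.01


class TestWaveform:
    def test_zero_ions_is_pure_baseline(self, rng):
        cfg = WaveformConfig(baseline_sd=0.01)
        wf = simulate_waveform([np.empty(0)] * 50, cfg, 3.2e-6, rng)
        assert wf.samples.std() == pytest.approx(0.01, rel=0.05)
        assert abs(wf.samples.mean()) < 0.001

    def test_single_isolated_pulse_geometry(self, rng):
        cfg = WaveformConfig(baseline_sd=0.001)
        wf = simulate_waveform([np.array([0.163])], cfg, 3.2e-6, rng)
        peak = wf.samples.max()
        assert 0.163 - 3 * cfg.baseline_sd <= peak <= 0.163 + 3 * cfg.baseline_sd
        # measured FWHM within one sample of the configured 160 ns
        above = np.flatnonzero(wf.samples >= peak / 2)
        fwhm = (above[-1] - above[0]) * cfg.sample_interval
        assert abs(fwhm - cfg.pulse_fwhm) <= 1.5 * cfg.sample_interval

    def test_interarrival_fraction_matches_exponential_law(self, rng):
        # detected arrivals at rate Lambda*(1-e^-eta): fraction of gaps
        # shorter than tau is 1 - exp(-rate*tau), the pile-up loss of Eq. gamma
        lam_rate, eta, tau = 0.68e6, 2.0, 0.13e-6
        dwell = 32e-6
        dose = lam_rate * dwell
        n_pix = 2000
        counts = rng.poisson(dose * -math.expm1(-eta), n_pix)
        amps = [np.full(c, 0.3) for c in counts]
        cfg = WaveformConfig(baseline_sd=0.0)
        _, arrivals = simulate_waveform(amps, cfg, dwell, rng, return_arrivals=True)
        gaps = np.diff(arrivals)
        frac = np.mean(gaps < tau)
        expected = 1.0 - 0.9264
        se = math.sqrt(expected * (1 - expected) / len(gaps))
        assert abs(frac - expected) < 4 * se

    def test_biexponential_kernel_fwhm(self, rng):
        cfg = WaveformConfig(baseline_sd=0.0, pulse_shape="biexponential")
        wf = simulate_waveform([np.array([1.0])], cfg, 3.2e-6, rng)
        peak = wf.samples.max()
        assert peak == pytest.approx(1.0, rel=0.02)
        above = np.flatnonzero(wf.samples >= 0.5 * peak)
        fwhm = (above[-1] - above[0]) * cfg.sample_interval
        assert fwhm == pytest.approx(cfg.pulse_fwhm, rel=0.15)


class TestPhantom:
    def test_squares_defaults(self):
        ph = make_phantom("squares", (32, 32))
        vals = np.unique(ph.eta_map)
        assert set(np.round(vals, 2)) == {1.82, 2.75}

    def test_uniform(self):
        ph = make_phantom("uniform", (4, 4), eta=1.0)
        assert ph.eta_map.shape == (4, 4)
        np.testing.assert_array_equal(ph.eta_map, 1.0)
        ph2 = make_phantom("uniform", (8, 8), eta=3.62)
        np.testing.assert_array_equal(ph2.eta_map, 3.62)

    def test_unknown_pattern(self):
        with pytest.raises(ValueError):
            make_phantom("checkerboard", (8, 8))


class TestSimulateImage:
    def test_zero_yield_gives_zero_measurements(self, rng):
        ph = make_phantom("uniform", (16, 16), eta=0.0)
        params = ModelParams(dose=10.0, yield_eta=0.0)
        sim = simulate_image(ph, params, rng)
        assert sim["v"].sum() == 0 and sim["m_tilde"].sum() == 0

    def test_conventional_estimate_unbiased_over_uniform_phantom(self, rng):
        ph = make_phantom("uniform", (256, 256), eta=2.0)
        params = ModelParams(dose=22.0, yield_eta=2.0, c_mu=C_MU, c_sigma=C_SIGMA)
        sim = simulate_image(ph, params, rng)
        est = sim["v"] / (C_MU * 22.0)
        se = est.std(ddof=1) / math.sqrt(est.size)
        assert abs(est.mean() - 2.0) < 3 * se

    def test_squares_phantom_background_mean(self, rng):
        ph = make_phantom("squares", (128, 128))
        params = ModelParams(dose=21.0, yield_eta=1.82, c_mu=C_MU, c_sigma=C_SIGMA)
        sim = simulate_image(ph, params, rng)
        bg = ph.eta_map == 1.82
        est = sim["v"][bg] / (C_MU * 21.0)
        se = est.std(ddof=1) / math.sqrt(bg.sum())
        assert abs(est.mean() - 1.82) < 3 * se
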