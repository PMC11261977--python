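"""Pulse detection on synthetic waveforms and pile-up correction."""

import math

import numpy as np
import pytest
from scipy import stats

from icam.model import ModelParams, detected_count_mean, pulse_height_density
from icam.pulses import (
    PileupConfig,
    calibrate_dead_time,
    correct_count,
    correct_count_selfconsistent,
    detect_pulses,
    pileup_gamma,
)
from icam.synth import WaveformConfig, Waveform, simulate_pixels, simulate_waveform

from conftest import C_MU, C_SIGMA


class TestDetectPulses:
    def test_flat_trace_finds_nothing(self):
        wf = Waveform(samples=np.zeros(3200), sample_interval=10e-9,
                      pixel_boundaries=np.array([0, 1600, 3200]))
        m, heights = detect_pulses(wf, PileupConfig(detection_threshold=0.05))
        assert m.tolist() == [0, 0]
        assert all(len(h) == 0 for h in heights)

    def test_well_separated_pulses_counted_exactly(self, rng):
        cfg = WaveformConfig(baseline_sd=0.01)
        amps_true = rng.uniform(0.15, 0.8, 100)
        # one pulse per pixel: guaranteed separation of one dwell (3.2 us)
        wf = simulate_waveform([np.array([a]) for a in amps_true], cfg, 3.2e-6, rng)
        m, heights = detect_pulses(wf, PileupConfig(detection_threshold=0.05),
                                   baseline_sd=cfg.baseline_sd)
        assert m.sum() == 100
        got = np.concatenate(heights)
        # pixel-ordered: one height per pixel, compare within noise
        assert np.all(np.abs(np.sort(got) - np.sort(amps_true)) < 3 * cfg.baseline_sd + 0.02)

    def test_two_overlapping_pulses_merge(self, rng):
        # two kernels 50 ns apart (< FWHM) are unimodal: one detection
        cfg = WaveformConfig(baseline_sd=0.0)
        kernel_sd = cfg.pulse_fwhm / (2 * math.sqrt(2 * math.log(2)))
        n = 2000
        t = (np.arange(n) - n / 2) * cfg.sample_interval
        trace = np.exp(-0.5 * (t / kernel_sd) ** 2) + np.exp(
            -0.5 * ((t - 50e-9) / kernel_sd) ** 2
        )
        wf = Waveform(samples=trace, sample_interval=cfg.sample_interval,
                      pixel_boundaries=np.array([0, n]))
        m, _ = detect_pulses(wf, PileupConfig(detection_threshold=0.05))
        assert m.tolist() == [1]

    def test_threshold_robustness(self, rng):
        # counts stable within ~1% when threshold sweeps [4, 8] x baseline sd,
        # run at a yield high enough that the pulse-height density has little
        # mass inside the 0.04-0.08 V threshold window
        cfg = WaveformConfig(baseline_sd=0.01)
        params = ModelParams(dose=5.0, yield_eta=4.0, c_mu=C_MU, c_sigma=C_SIGMA)
        sim = simulate_pixels(params, 2000, rng, return_pulses=True)
        per_pixel = np.split(
            sim["pulse_heights"],
            np.cumsum(np.bincount(sim["pulse_pixel"], minlength=2000))[:-1],
        )
        wf = simulate_waveform(per_pixel, cfg, 32e-6, rng)
        counts = []
        for mult in (4, 5, 6, 7, 8):
            m, _ = detect_pulses(
                wf, PileupConfig(detection_threshold=mult * cfg.baseline_sd)
            )
            counts.append(m.sum())
        assert (max(counts) - min(counts)) / max(counts) < 0.015


class TestPileupGamma:
    def test_paper_operating_point(self):
        assert pileup_gamma(0.68e6, 2.0, 0.13e-6) == pytest.approx(0.92641, abs=1e-5)

    def test_no_dead_time_no_correction(self):
        assert pileup_gamma(0.68e6, 2.0, 0.0) == 1.0
        assert pileup_gamma(0.68e6, 0.0, 0.13e-6) == 1.0

    def test_correct_count_division(self):
        assert correct_count(100, 0.68e6, 2.0, 0.13e-6) == pytest.approx(107.94, abs=0.01)
        assert correct_count(100, 0.68e6, 2.0, 0.0) == 100.0

    def test_monotone_in_each_argument(self):
        base = correct_count(100, 0.5e6, 1.5, 0.1e-6)
        assert correct_count(100, 0.6e6, 1.5, 0.1e-6) > base
        assert correct_count(100, 0.5e6, 2.0, 0.1e-6) > base
        assert correct_count(100, 0.5e6, 1.5, 0.12e-6) > base

    def test_gamma_floor_rejected(self):
        with pytest.raises(ValueError, match="pile-up"):
            correct_count(100, 20e6, 3.0, 1e-6)


def _detectable_fraction(eta, threshold):
    """Model PHD mass above the detection threshold: pulses below it are
    physically undetectable whatever the processing."""
    u = np.linspace(threshold, 8.0, 20000)
    f = pulse_height_density(u, eta, C_MU, C_SIGMA)
    return float(np.trapezoid(f, u))


class TestEndToEnd:
    def _simulate_and_detect(self, rng, n_pix, dwell, dose_rate, eta,
                             baseline_sd=0.002, threshold=0.02):
        dose = dose_rate * dwell
        params = ModelParams(dose=dose, yield_eta=eta, c_mu=C_MU, c_sigma=C_SIGMA)
        sim = simulate_pixels(params, n_pix, rng, return_pulses=True)
        per_pixel = np.split(
            sim["pulse_heights"],
            np.cumsum(np.bincount(sim["pulse_pixel"], minlength=n_pix))[:-1],
        )
        cfg = WaveformConfig(baseline_sd=baseline_sd)
        wf = simulate_waveform(per_pixel, cfg, dwell, rng)
        m, heights = detect_pulses(wf, PileupConfig(detection_threshold=threshold),
                                   baseline_sd=cfg.baseline_sd)
        return sim, per_pixel, m, heights

    def test_pileup_correction_restores_mean_count(self, rng):
        # The dead time of a real pipeline is set by the pulse shape and the
        # peak finder together, so it is calibrated on a run at a different
        # dose rate; the exponential gamma model must then transfer it to the
        # operating point (0.6875 ions/us = 0.11 pA, 32 us dwell -> dose 22).
        dwell, eta = 32e-6, 2.0
        q = _detectable_fraction(eta, 0.02)

        cal_rate = 1.2e6
        sim_c, _, m_c, _ = self._simulate_and_detect(rng, 4000, dwell, cal_rate, eta)
        expected_c = detected_count_mean(cal_rate * dwell, eta) * q
        pulse_rate_c = expected_c / dwell
        tau_hat = calibrate_dead_time(m_c.mean() / expected_c, pulse_rate_c)

        dose_rate = 0.6875e6
        dose = dose_rate * dwell
        sim, _, m, heights = self._simulate_and_detect(rng, 6000, dwell, dose_rate, eta)
        expected = detected_count_mean(dose, eta) * q
        raw_deficit = (expected - m.mean()) / expected
        assert raw_deficit > 0.05  # uncorrected counts visibly undercount
        v = np.array([h.sum() for h in heights])
        m_corr, eta_used = correct_count_selfconsistent(
            m.astype(float), v, dose, dose_rate, C_MU, tau_hat
        )
        assert abs(m_corr.mean() - expected) / expected < 0.01
        assert abs(eta_used - eta) < 0.1

    def test_low_pileup_waveform_recovers_tuples(self, rng):
        # negligible pile-up: detected counts match the detectable truth
        # (amplitudes above threshold) pixel for pixel
        dose_rate, dwell, eta = 0.02e6, 32e-6, 2.0
        sim, per_pixel, m, heights = self._simulate_and_detect(
            rng, 4000, dwell, dose_rate, eta
        )
        truth_detectable = np.array([(a >= 0.02).sum() for a in per_pixel])
        agree = np.mean(m == truth_detectable)
        assert agree >= 0.99
        # and recovered heights match the simulated amplitudes
        for k in range(0, 4000, 503):
            if m[k] and m[k] == truth_detectable[k]:
                a = np.sort(per_pixel[k][per_pixel[k] >= 0.02])
                np.testing.assert_allclose(np.sort(heights[k]), a, atol=0.02)

    def test_peak_height_distribution_matches_model(self, rng):
        # chi-square goodness of fit of detected heights against the
        # pulse-height density, conditioned above the detection threshold
        dose_rate, dwell, eta = 0.01e6, 32e-6, 2.0
        sim, _, m, heights = self._simulate_and_detect(rng, 60000, dwell, dose_rate, eta)
        h = np.concatenate([x for x in heights])
        lo = 0.15  # clear of threshold effects
        h = h[h >= lo]
        edges = np.quantile(h, np.linspace(0, 1, 21))
        edges[0], edges[-1] = lo, h.max() + 1e-6
        obs, _ = np.histogram(h, edges)
        u = np.linspace(lo, edges[-1] + 0.5, 4000)
        dens = pulse_height_density(u, eta, C_MU, C_SIGMA)
        cdf = np.concatenate([[0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(u))])
        probs = np.interp(edges, u, cdf)
        p_bins = np.diff(probs) / (probs[-1] - probs[0])
        chi2, p = stats.chisquare(obs, f_exp=p_bins * obs.sum(), ddof=0)
        assert p > 0.01
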