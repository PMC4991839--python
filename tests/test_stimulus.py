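"""Stimulus generators: OU statistics, biexponential events, protocols."""

import numpy as np
import pytest

import isrtools as it
from isrtools.stimulus import biexp_kernel_norm


class TestOU:
    def test_zero_sigma_is_constant(self):
        wf = it.ou_series(it.OUSpec(mu=-150.0, sigma=0.0, tau=2.0), 0.1, 100,
                          seed=0)
        assert np.all(wf.samples == -150.0)

    def test_stationary_moments(self):
        # mean and SD of a long series within 3 standard errors
        mu, sigma, tau, dt = -150.0, 30.0, 2.0, 0.1
        n = 1_000_000
        wf = it.ou_series(it.OUSpec(mu, sigma, tau), dt, n, seed=7)
        x = wf.samples
        se_mean = sigma * np.sqrt(2 * tau / (n * dt))
        assert abs(x.mean() - mu) < 3 * se_mean
        assert abs(x.std() - sigma) < 3 * sigma / np.sqrt(n * dt / (2 * tau))

    def test_lag_tau_autocorrelation(self):
        tau, dt = 2.0, 0.1
        n = 1_000_000
        x = it.ou_series(it.OUSpec(0.0, 30.0, tau), dt, n, seed=8).samples
        k = int(tau / dt)
        r = np.corrcoef(x[:-k], x[k:])[0, 1]
        assert r == pytest.approx(np.exp(-1.0), abs=0.01)

    def test_deterministic_given_seed(self):
        a = it.ou_series(it.OUSpec(0, 10, 2), 0.1, 1000, seed=3).samples
        b = it.ou_series(it.OUSpec(0, 10, 2), 0.1, 1000, seed=3).samples
        assert np.array_equal(a, b)


class TestDualOU:
    def test_zero_sigma(self):
        wf = it.dual_ou_current(-100.0, 0.0, 0.1, seed=1, noise_ms=1000.0)
        assert np.all(wf.samples == -100.0)

    def test_total_sd_matches(self):
        wf = it.dual_ou_current(0.0, 153.0, 0.1, seed=2, noise_ms=60_000.0)
        noise = wf.samples[wf.segments[-1].start:]
        assert noise.std() == pytest.approx(153.0, rel=0.03)

    def test_autocovariance_is_two_exponential_mix(self):
        sigma, dt = 153.0, 0.1
        wf = it.dual_ou_current(0.0, sigma, dt, seed=4, noise_ms=200_000.0)
        x = wf.samples[wf.segments[-1].start:]
        x = x - x.mean()
        for lag_ms in (1.0, 5.0, 15.0):
            k = int(lag_ms / dt)
            emp = np.mean(x[:-k] * x[k:])
            expected = 0.5 * sigma ** 2 * (np.exp(-lag_ms / 3.0)
                                           + np.exp(-lag_ms / 10.0))
            assert emp == pytest.approx(expected, rel=0.08)

    def test_lead_in_silent(self):
        wf = it.dual_ou_current(-50.0, 100.0, 0.1, seed=5, lead_ms=500.0,
                                noise_ms=1000.0)
        assert np.all(wf.samples[:5000] == -50.0)


class TestBiexp:
    def test_no_events_all_zero(self):
        wf = it.biexp_current(it.BiexpInputSpec((), 100.0), 0.1, 1000)
        assert np.all(wf.samples == 0.0)

    def test_single_event_peaks_at_amplitude(self):
        # oracle: dense-grid maximization of the closed-form kernel
        wf = it.biexp_current(it.BiexpInputSpec((50.0,), 100.0), 0.01, 50_000)
        assert wf.samples.max() == pytest.approx(100.0, rel=1e-3)

    def test_event_integral_closed_form(self):
        # integral of (e^{-t/tau2}-e^{-t/tau1})/(tau2-tau1) is 1, so each
        # event integrates to Am/K
        Am, t1, t2 = 80.0, 1.5, 10.0
        wf = it.biexp_current(it.BiexpInputSpec((10.0,), Am, t1, t2), 0.01,
                              40_000)
        assert np.trapezoid(wf.samples, dx=0.01) == pytest.approx(
            Am / biexp_kernel_norm(t1, t2), rel=1e-3)

    def test_events_sum_linearly(self):
        one = it.biexp_current(it.BiexpInputSpec((20.0,), 50.0), 0.1, 2000)
        two = it.biexp_current(it.BiexpInputSpec((20.0, 21.0), 50.0), 0.1,
                               2000)
        shifted = it.biexp_current(it.BiexpInputSpec((21.0,), 50.0), 0.1,
                                   2000)
        assert np.allclose(two.samples, one.samples + shifted.samples)

    def test_equal_time_constants_rejected(self):
        with pytest.raises(ValueError):
            it.BiexpInputSpec((0.0,), 10.0, tau1=5.0, tau2=5.0)

    def test_event_outside_range_rejected(self):
        with pytest.raises(ValueError):
            it.biexp_current(it.BiexpInputSpec((300.0,), 10.0), 0.1, 1000)


class TestProtocols:
    def test_noise_steps_annotations(self):
        sigmas = np.arange(0.0, 501.0, 50.0)
        wf = it.build_protocol("noise_steps", dt=0.1, mean=-100.0,
                               sigmas=sigmas, seed=0)
        noise_segs = [s for s in wf.segments if s.label == "noise"]
        assert len(noise_segs) == 11
        assert [s.sigma for s in noise_segs] == list(sigmas)
        # segments reconstruct the waveform layout exactly
        total = sum(s.n for s in wf.segments)
        assert total == wf.n

    def test_ramp_peak_is_rate_times_duration(self):
        wf = it.build_protocol("ramp", dt=0.1, I_start=-650.0,
                               rate_pA_per_ms=0.9, up_ms=1000.0, trials=1)
        assert wf.samples.max() == pytest.approx(-650.0 + 0.9 * 1000.0,
                                                 abs=0.1)

    def test_current_steps_layout(self):
        wf = it.build_protocol("current_steps", dt=0.1, I_start=-650.0)
        steps = [s for s in wf.segments if s.label == "step"]
        assert len(steps) == 30
        incs = np.diff([s.mean for s in steps])
        assert np.allclose(incs, 50.0)

    def test_pulse_width_and_amplitude(self):
        wf = it.build_protocol("pulse", dt=0.01, hold=-200.0, amp=1000.0,
                               width_ms=0.5, t_pulse_ms=100.0)
        assert wf.samples.max() == pytest.approx(800.0)
        assert np.sum(wf.samples > 0) == 50  # 0.5 ms at 0.01 ms

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            it.build_protocol("zap")
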