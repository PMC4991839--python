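"""Response statistics: ISR curves, hysteresis, f-I, PSTH, histograms."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import isrtools as it


class TestDetectSpikes:
    def test_flat_trace_empty(self):
        tr = it.VoltageTrace(dt=0.1, V=np.full(1000, -55.0),
                             I_in=np.zeros(1000))
        assert len(it.detect_spikes(tr)) == 0

    def test_matches_integrator_log_on_recording(self, rep):
        wf = it.ou_series(it.OUSpec(-150.0, 60.0, 2.0), 0.05, 100_000,
                          seed=21)
        spec = it.SyntheticCellSpec(params=rep, seed=1, fs_khz=10.0,
                                    noise_sd_mV=0.0)
        init = (-54.5, -120.0)  # near the rest state
        rec = it.synth_recording(spec, wf, init=init)
        _, train, _ = it.integrate(rep, wf, init=init, dt=0.05,
                                   record=False)
        det = it.detect_spikes(rec)
        assert len(det) == len(train)
        assert np.max(np.abs(det.times_ms - train.times_ms)) < 0.25

    def test_refractory_merges_close_crossings(self):
        V = np.full(1000, -60.0)
        V[100:102] = 0.0   # two crossings 1 ms apart at dt=0.5
        V[102] = -60.0
        V[103:105] = 0.0
        tr = it.VoltageTrace(dt=0.5, V=V, I_in=np.zeros(1000))
        assert len(it.detect_spikes(tr, refractory_ms=2.0)) == 1


class TestISRCurve:
    def test_argmin_of_known_epochs(self):
        epochs = []
        rates = {0.0: 40, 10.0: 35, 20.0: 10, 30.0: 12, 40.0: 25}
        for s, r in rates.items():
            epochs += [(s, r, 1000.0)] * 3
        c = it.isr_curve(epochs, smoothing_pA=1e-6)
        assert c.sigma_opt == 20.0
        assert not c.flat

    def test_flat_curve_flagged(self):
        epochs = [(s, 10, 1000.0) for s in (0.0, 10.0, 20.0) for _ in
                  range(3)]
        with pytest.warns(UserWarning):
            c = it.isr_curve(epochs)
        assert c.flat

    def test_needs_three_sigmas(self):
        with pytest.raises(ValueError):
            it.isr_curve([(0.0, 1, 1000.0), (10.0, 2, 1000.0)])

    def test_model_minimum_at_intermediate_noise(self, rep):
        c = it.isr_curve_from_model(rep, -150.0,
                                    np.arange(0.0, 70.0, 10.0),
                                    reps=4, T_ms=10_000.0, seed=9)
        assert 20.0 <= c.sigma_opt <= 40.0
        assert c.rate[0] > 15.0  # sustained firing without noise


@pytest.fixture(scope="module")
def continuous_recording(rep):
    proto = it.build_protocol("continuous_noise", dt=0.1, mean=-150.0,
                              sigma_max=120.0, rate_pA_per_ms=0.05,
                              cycles=6, seed=14)
    spec = it.SyntheticCellSpec(params=rep, seed=3, fs_khz=10.0,
                                noise_sd_mV=0.1)
    return it.synth_recording(spec, proto, init=(-40.0, 0.0))


class TestContinuousISR:
    def test_bistable_history_dependence(self, continuous_recording):
        recording = continuous_recording
        was_firing, was_silent = it.isr_curve_continuous(recording)
        assert len(was_firing.sigma) >= 4 and len(was_silent.sigma) >= 4
        # firing-history curve has an interior minimum (ISR)
        k = int(np.argmin(was_firing.smoothed))
        assert 0 < k < len(was_firing.sigma) - 1
        # silent-history curve starts near zero and grows with noise
        assert was_silent.rate[0] < 5.0
        rho = spearmanr(was_silent.sigma, was_silent.rate).statistic
        assert rho > 0.5

    def test_all_silent_trace_handled(self):
        tr = it.VoltageTrace(dt=0.1, V=np.full(20_000, -60.0),
                             I_in=np.zeros(20_000),
                             meta={"sigma_samples": np.linspace(0, 100,
                                                               20_000)})
        was_firing, was_silent = it.isr_curve_continuous(tr)
        assert len(was_firing.sigma) == 0 or np.all(was_firing.rate == 0)

    def test_missing_annotation_rejected(self):
        tr = it.VoltageTrace(dt=0.1, V=np.zeros(100) - 60, I_in=np.zeros(100))
        with pytest.raises(ValueError):
            it.isr_curve_continuous(tr)


class TestHysteresis:
    def test_representative_has_positive_hysteresis(self, rep):
        h = it.hysteresis_ramp(rep)
        assert h.delta_I > 0
        assert h.delta_f > 0

    def test_type_i_has_negligible_hysteresis(self, type1_params):
        h = it.hysteresis_ramp(type1_params)
        sd = max(h.per_trial["I_up"].std() + h.per_trial["I_down"].std(),
                 5.0)
        assert abs(h.delta_I) < 3 * sd + 10.0

    def test_ramp_onset_overshoots_into_hopf_fold_gap(self, rep):
        # the noise-free ramp passes the Hopf point with a delayed onset: the
        # first spike lands between the Hopf current and the subthreshold
        # fold, and does not converge to the closed-form rheobase
        h = it.hysteresis_ramp(rep, rate_pA_per_ms=0.09, up_ms=10_000.0)
        i_hopf = it.rheobase_up(rep)
        assert i_hopf < h.I_up < i_hopf + 15.0


class TestFICurve:
    def test_type_ii_discontinuity(self, rep):
        r = it.fi_curve(rep)
        assert r["f_min_onset"] > 5.0  # nonzero minimum firing frequency

    def test_all_subthreshold_steps_silent(self, rep):
        r = it.fi_curve(rep, I_start=-800.0, n_steps=5, dI=50.0)
        assert np.all(r["f"] == 0.0)

    def test_suprathreshold_region_linear(self, rep):
        r = it.fi_curve(rep)
        m = r["f"] > 0
        I, f = r["I"][m], r["f"][m]
        coef = np.polyfit(I, f, 1)
        ss_res = np.sum((f - np.polyval(coef, I)) ** 2)
        ss_tot = np.sum((f - f.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.95


class TestPSTH:
    def test_no_stimulus_is_flat_at_baseline(self, rep, basin150):
        r = it.psth(rep, 0.0, 40.0, sweeps=60, T_ms=6000.0, seed=5,
                    basin=basin150)
        post = r.p[r.t_centers_ms >= r.t_st_ms]
        assert abs(post.mean() - r.baseline) < 0.12

    def test_low_noise_latch(self, rep, basin150):
        # sigma = 10 pA: pre-stimulus silence, post-stimulus persistent firing
        r = it.psth(rep, 100.0, 10.0, sweeps=60, seed=6, basin=basin150)
        assert r.baseline < 0.05
        post = r.p[r.t_centers_ms >= r.t_st_ms + 500.0]
        assert post.mean() > 0.6

    def test_optimal_noise_transient(self, rep, basin150):
        # sigma = 30 pA: elevation that decays back toward zero
        r = it.psth(rep, 100.0, 30.0, sweeps=100, seed=7, basin=basin150)
        assert r.baseline < 0.1
        post = r.p[r.t_centers_ms >= r.t_st_ms]
        assert post.max() > 0.4
        assert post[-10:].mean() < 0.2
        d = it.decay_time_constant(r)
        assert not d["infinite"]
        assert 0.1 < d["tau_s"] < 3.0

    def test_decay_recovers_synthetic_exponential(self):
        edges = np.arange(0, 6001.0, 20.0)
        t = 0.5 * (edges[:-1] + edges[1:])
        tau_true = 0.8
        p = np.where(t < 3000.0, 0.01,
                     0.01 + 0.7 * np.exp(-(t - 3000.0) / (tau_true * 1000)))
        r = it.PSTHResult(bin_edges_ms=edges, p=p, p_spike=p, sweeps=1,
                          t_st_ms=3000.0, baseline=0.01, mode="basin")
        d = it.decay_time_constant(r)
        assert d["tau_s"] == pytest.approx(tau_true, rel=0.05)

    def test_noise_free_latch_flagged_infinite(self, rep, basin150):
        r = it.psth(rep, 100.0, 0.0, sweeps=3, seed=8, basin=basin150)
        d = it.decay_time_constant(r)
        assert d["infinite"]

    def test_decay_shortens_with_noise(self, rep, basin150):
        taus = {}
        for s in (20.0, 50.0):
            r = it.psth(rep, 100.0, s, sweeps=150, seed=9, basin=basin150)
            taus[s] = it.decay_time_constant(r)["tau_s"]
        assert taus[50.0] < taus[20.0]


class TestVmHistogram:
    def test_bimodal_in_noisy_bistable_regime(self, rep, basin150):
        wf = it.ou_series(it.OUSpec(-150.0, 60.0, 2.0), 0.1, 300_000,
                          seed=10)
        trace, train, w = it.integrate(rep, wf, init=(-40.0, 0.0))
        labels = np.zeros(trace.n, bool)
        # spiking state: within 60 ms of a spike
        for t in train.times_ms:
            k = int(t / 0.1)
            labels[k:k + 600] = True
        h = it.vm_histogram(trace, labels)
        for k in ("spiking", "silent", "pooled"):
            d, e = h[k]["density"], h[k]["edges"]
            assert np.sum(d * np.diff(e)) == pytest.approx(1.0, abs=1e-6)
        # the two state distributions occupy different voltages
        mode_sp = h["spiking"]["edges"][np.argmax(h["spiking"]["density"])]
        mode_si = h["silent"]["edges"][np.argmax(h["silent"]["density"])]
        assert abs(mode_sp - mode_si) > 1.0

    def test_silent_only_unimodal_near_fixed_point(self, rep, basin150):
        fp = basin150.fixed_point
        wf = it.ou_series(it.OUSpec(-150.0, 5.0, 2.0), 0.1, 100_000, seed=11)
        trace, _, _ = it.integrate(rep, wf, init=(fp.V, fp.w))
        h = it.vm_histogram(trace, np.zeros(trace.n, bool))
        peak = h["silent"]["edges"][np.argmax(h["silent"]["density"])]
        assert abs(peak - fp.V) < 2.0
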