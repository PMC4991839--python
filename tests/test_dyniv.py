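"""Dynamic I-V pipeline: stage estimators and full-fit recovery."""

import numpy as np
import pytest

import isrtools as it
from isrtools.dyniv import SpikeExclusion


@pytest.fixture(scope="module")
def rc_recording(rep):
    """Passive cell (a = b = 0, threshold pushed away): pure RC ground truth."""
    p = rep.with_(a=0.0, b=0.0, DeltaT=0.3, VT=-20.0)
    proto = it.dual_ou_current(mean=-100.0, sigma=80.0, dt=0.01, seed=31,
                               noise_ms=10_000.0)
    spec = it.SyntheticCellSpec(params=p, seed=32, noise_sd_mV=0.05)
    return p, it.synth_recording(spec, proto, init=(p.EL, 0.0))


class TestCapacitance:
    def test_rc_cell_exact_recovery(self, rc_recording):
        p, rec = rc_recording
        est = it.estimate_capacitance(rec)
        assert est.Ce == pytest.approx(p.C, rel=0.02)
        assert est.unimodal

    def test_requires_enough_data(self, rc_recording):
        _, rec = rc_recording
        short = it.VoltageTrace(dt=rec.dt, V=rec.V[:50_000],
                                I_in=rec.I_in[:50_000])
        with pytest.raises(ValueError):
            it.estimate_capacitance(short)


class TestIVCurve:
    def test_pure_leak_is_line_through_EL(self, rc_recording):
        p, rec = rc_recording
        curve = it.dynamic_iv_curve(rec, p.C)
        slope, inter = np.polyfit(curve.V, curve.I_dyn, 1)
        assert slope == pytest.approx(p.gL, rel=0.05)
        # zero crossing at EL
        assert -inter / slope == pytest.approx(p.EL, abs=0.5)

    def test_bin_scatter_is_roughly_gaussian(self, bundle):
        # per-bin distribution sanity: skewness small at an interior bin
        tr = bundle["dyniv_noise"]
        est = it.estimate_capacitance(tr)
        d = np.empty(tr.n)
        d[1:-1] = (tr.V[2:] - tr.V[:-2]) / (2 * tr.dt)
        d[0] = d[-1] = 0
        Im = tr.I_in - est.Ce * d
        spk = it.detect_spikes(tr)
        inc = SpikeExclusion().mask(tr.n, tr.dt,
                                    (spk.times_ms / tr.dt).astype(np.int64))
        m = inc & (np.abs(tr.V - (-56.0)) < 0.5)
        x = Im[m]
        from scipy.stats import skew
        assert abs(skew(x)) < 0.5


class TestEIFFit:
    def test_exact_curve_recovered(self):
        # curve synthesized exactly from the EIF form
        V = np.arange(-70.0, -46.0, 1.0)
        tm, EL, VT, DT, C = 8.0, -51.31, -53.23, 0.85, 200.0
        F = (EL - V + DT * np.exp((V - VT) / DT)) / tm
        curve = it.DynamicIVCurve(V=V, I_dyn=-F * C,
                                  sd=np.full(len(V), 1.0),
                                  count=np.full(len(V), 1000.0), Ce=C)
        fit = it.fit_eif(curve)
        assert fit.tau_m_dyn == pytest.approx(tm, rel=1e-4)
        assert fit.EL == pytest.approx(EL, abs=1e-3)
        assert fit.VT == pytest.approx(VT, abs=1e-3)
        assert fit.DeltaT == pytest.approx(DT, rel=1e-3)

    def test_narrow_curve_rejected(self):
        V = np.arange(-56.0, -52.0, 1.0)
        curve = it.DynamicIVCurve(V=V, I_dyn=V * 10.0, sd=np.ones(len(V)),
                                  count=np.full(len(V), 100.0), Ce=200.0)
        with pytest.raises(ValueError):
            it.fit_eif(curve)


class TestSubthresholdA:
    def test_zero_adaptation_cell(self, rc_recording):
        p, rec = rc_recording
        curve = it.dynamic_iv_curve(rec, p.C)
        a = it.estimate_subthreshold_a(curve, p.gL,
                                       window=(p.EL - 12.0, p.EL + 6.0))
        assert abs(a) < 0.15 * p.gL

    def test_window_needs_five_bins(self, rc_recording):
        p, rec = rc_recording
        curve = it.dynamic_iv_curve(rec, p.C)
        with pytest.raises(ValueError):
            it.estimate_subthreshold_a(curve, p.gL,
                                       window=(p.EL, p.EL + 2.0))


class TestPulse:
    def test_single_exponential_recovery(self):
        # synthetic single-exponential decay after a pulse
        dt = 0.02
        n = 20_000
        t = np.arange(n) * dt
        I = np.zeros(n)
        I[5000:5025] = 1000.0
        V = np.full(n, -60.0)
        post = t >= t[5025]
        V[post] = -60.0 + 3.0 * np.exp(-(t[post] - t[5025]) / 12.0)
        tr = it.VoltageTrace(dt=dt, V=V, I_in=I)
        fit = it.fit_membrane_tau_pulse(tr)
        assert fit.mode in ("single", "biexp")
        assert fit.tau_m == pytest.approx(12.0, rel=0.1)

    def test_two_compartment_constants_recovered(self, rep):
        # oracle: eigenvalues of the passive two-compartment system
        soma = rep.with_(a=1e-6, b=0.0, DeltaT=0.3, VT=-20.0)
        tc = it.TwoCompartmentParams(soma=soma, gc=10.2, Cd=500.0, gLd=20.0)
        proto = it.build_protocol("pulse", dt=0.005, hold=-150.0,
                                  t_pulse_ms=300.0, total_ms=700.0)
        trace, _, _ = it.integrate(tc, proto, dt=0.005)
        fit = it.fit_membrane_tau_pulse(trace)
        A = np.array([
            [-(soma.gL + tc.gc) / soma.C, tc.gc / soma.C],
            [tc.gc / tc.Cd, -(tc.gLd + tc.gc) / tc.Cd],
        ])
        lam = np.sort(np.linalg.eigvals(A))  # both negative
        tau_slow, tau_fast = -1.0 / lam[1], -1.0 / lam[0]
        assert fit.mode == "biexp"
        assert fit.tau_m == pytest.approx(tau_slow, rel=0.1)
        assert fit.tau_c == pytest.approx(tau_fast, rel=0.15)

    def test_representative_pulse_is_oscillatory(self, bundle):
        # strong slow adaptation makes the rest state a focus; the pulse
        # relaxation rings and the damped-cosine branch reports it
        fit = it.fit_membrane_tau_pulse(bundle["pulse"])
        assert fit.mode == "damped_osc"
        assert fit.omega > 0


class TestSpikeAdaptation:
    def test_needs_spikes(self, rc_recording):
        p, rec = rc_recording
        with pytest.raises(ValueError):
            it.fit_spike_adaptation(rec, p.C, p.gL, 0.0, p.EL)

    def test_zero_b_cell_fits_small_amplitude(self, rep):
        # b ~ 0: the spike-triggered component vanishes
        p = rep.with_(b=1e-6)
        proto = it.dual_ou_current(mean=-250.0, sigma=200.0, dt=0.01,
                                   seed=41, noise_ms=15_000.0)
        spec = it.SyntheticCellSpec(params=p, seed=42)
        rec = it.synth_recording(spec, proto)
        est = it.estimate_capacitance(rec)
        curve = it.dynamic_iv_curve(rec, est.Ce)
        eif = it.fit_eif(curve)
        fit = it.fit_spike_adaptation(rec, est.Ce, eif.slope_nS, 0.0, eif.EL,
                                      VT_cut=eif.VT)
        assert fit.b < 100.0  # noise floor, small vs population b ~ 408


class TestFullFit:
    def test_representative_recovery(self, rep_fit):
        fitted, report, truth = rep_fit
        tol = {"C": 0.05, "EL": 0.02, "VT": 0.03, "DeltaT": 0.2,
               "a": 0.15, "b": 0.2, "tau_w": 0.25}
        for k, t in tol.items():
            fv, tv = getattr(fitted, k), getattr(truth, k)
            assert abs(fv - tv) / abs(tv) < t, (k, fv, tv)

    def test_classification_preserved(self, rep_fit):
        fitted, _, truth = rep_fit
        assert it.classify_excitability(truth) == "type_II"
        assert it.classify_excitability(fitted) == "type_II"

    def test_refit_of_refit_is_stable(self, rep_fit, bundle):
        # fixed-point property: re-fitting a model simulated from the fitted
        # parameters returns them within the same tolerances
        fitted, _, _ = rep_fit
        proto = it.dual_ou_current(mean=0.0, sigma=153.0, dt=0.01, seed=51,
                                   noise_ms=15_000.0)
        spec = it.SyntheticCellSpec(params=fitted, seed=52)
        rec = it.synth_recording(spec, proto)
        refit, _ = it.fit_full(rec, None)
        for k, t in (("C", 0.05), ("EL", 0.02), ("VT", 0.03),
                     ("a", 0.15), ("b", 0.2), ("tau_w", 0.25)):
            fv, tv = getattr(refit, k), getattr(fitted, k)
            assert abs(fv - tv) / abs(tv) < t, (k, fv, tv)

    def test_missing_pulse_warns(self, bundle):
        with pytest.warns(UserWarning):
            params, _ = it.fit_full(bundle["dyniv_noise"], None,
                                    refine=False)

    def test_capacitance_objective_unimodal(self, rep_fit):
        _, report, _ = rep_fit
        assert report["capacitance"].unimodal
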