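"""Model definitions: derivatives, rescaling, excitability, rheobase."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import isrtools as it
from isrtools.params import TwoCompartmentParams, two_compartment_derivatives


def test_derivatives_at_leak_reversal(rep):
    # at V = EL with w = 0 the leak and adaptation terms vanish; only the
    # exponential drive remains, which is positive
    dV, dw = it.aeif_derivatives((rep.EL, 0.0), rep, 0.0)
    expected = rep.gL * rep.DeltaT * math.exp(
        (rep.EL - rep.VT) / rep.DeltaT) / rep.C
    assert dV == pytest.approx(expected, rel=1e-12)
    assert dw == 0.0


def test_derivatives_hand_evaluated(rep):
    # frozen independent evaluation of the right-hand side at V=-60, w=0,
    # I=0: -8.47*(-60+51.31) + 8.47*0.85*exp((-60+53.23)/0.85) over C=268
    dV, dw = it.aeif_derivatives((-60.0, 0.0), rep, 0.0)
    assert dV == pytest.approx(0.27465224599, rel=1e-9)
    assert dw == pytest.approx(37.79 * (-60.0 + 51.31) / 20.76, rel=1e-9)


def test_derivatives_small_deltat_is_leaky_integrator(rep):
    p = rep.with_(DeltaT=1e-6)
    V, w, I = -70.0, 25.0, -40.0
    dV, _ = it.aeif_derivatives((V, w), p, I)
    assert dV == pytest.approx((-p.gL * (V - p.EL) - w + I) / p.C, rel=1e-9)


def test_derivatives_nonfinite_state_rejected(rep):
    with pytest.raises(ValueError):
        it.aeif_derivatives((math.nan, 0.0), rep, 0.0)


def test_rescale_representative_values(rep):
    # arithmetic oracle: A = 37.79/8.47, tau_m = 268/8.47, T = 20.76/tau_m
    rs = it.rescale(rep, -150.0)
    assert rs.A == pytest.approx(4.46162, rel=1e-4)
    assert rs.T == pytest.approx(20.76 / (268.0 / 8.47), rel=1e-4)


def test_rescale_zero_adaptation(rep):
    assert it.rescale(rep.with_(a=0.0), 0.0).A == 0.0


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    a=st.floats(0.0, 80.0),
    tau_w=st.floats(2.0, 60.0),
    b=st.floats(0.0, 900.0),
    Vr=st.floats(-75.0, -50.0),
    I=st.floats(-400.0, 200.0),
)
def test_rescale_round_trip(a, tau_w, b, Vr, I):
    p = it.AEIFParams(C=268.0, gL=8.47, EL=-51.31, VT=-53.23, DeltaT=0.85,
                      a=a, b=b, tau_w=tau_w, Vr=Vr)
    q, I2 = it.rescale(p, I).restore(p)
    assert I2 == pytest.approx(I, abs=1e-9 * max(1.0, abs(I)))
    for f in ("a", "tau_w", "b", "Vr"):
        assert getattr(q, f) == pytest.approx(getattr(p, f),
                                              rel=1e-12, abs=1e-9)


def test_classification(rep, type1_params):
    assert it.classify_excitability(rep) == "type_II"
    assert it.classify_excitability(rep.with_(a=0.0)) == "type_I"
    assert it.classify_excitability(type1_params) == "type_I"
    # population-mean parameters (gL = C/tau_m from printed stats)
    pop = it.AEIFParams(C=195.4, gL=195.4 / 4.4, EL=-51.9, VT=-54.1,
                        DeltaT=1.0, a=36.1, b=408.0, tau_w=14.8, Vr=-60.0)
    assert it.classify_excitability(pop) == "type_II"


def test_classification_boundary_warns(rep):
    p = rep.with_(a=rep.gL * rep.tau_m / rep.tau_w)
    with pytest.warns(UserWarning):
        assert it.classify_excitability(p) == "type_I"


def test_rheobase_closed_form(rep):
    # frozen independent numeric evaluation of the closed form
    assert it.rheobase_up(rep) == pytest.approx(-70.584, abs=0.01)


def test_rheobase_requires_type_ii(type1_params):
    with pytest.raises(ValueError):
        it.rheobase_up(type1_params)


def test_rheobase_homogeneous_in_conductances(rep):
    # scaling C, gL, a, b by a common factor scales I_up by that factor
    k = 2.5
    scaled = rep.with_(C=k * rep.C, gL=k * rep.gL, a=k * rep.a, b=k * rep.b)
    assert it.rheobase_up(scaled) == pytest.approx(k * it.rheobase_up(rep),
                                                   rel=1e-12)


def test_two_compartment_limits(rep):
    tc = TwoCompartmentParams(soma=rep, gc=1e-9, Cd=150.0, gLd=10.0)
    dV, dw, dVd = two_compartment_derivatives((-60.0, 10.0, -55.0), tc,
                                              -100.0)
    ref = it.aeif_derivatives((-60.0, 10.0), rep, -100.0)
    assert dV == pytest.approx(ref[0], abs=1e-9)
    assert dw == pytest.approx(ref[1], abs=1e-12)
    # V = Vd = EL, w = 0, I = 0: dendrite is at rest
    _, _, dVd = two_compartment_derivatives((rep.EL, 0.0, rep.EL), tc, 0.0)
    assert dVd == 0.0


def test_two_compartment_steady_state_ordering(rep):
    # constant subthreshold hyperpolarizing current at the soma: solving the
    # 2x2 linear steady state puts Vd between EL and V
    soma = rep.with_(a=0.0, DeltaT=1e-6, VT=-20.0)
    tc = TwoCompartmentParams(soma=soma, gc=10.0, Cd=200.0, gLd=6.0)
    I = -100.0
    # steady state: gL(V-EL) + gc(V-Vd) = I ; gLd(Vd-EL) = gc(V-Vd)
    A = np.array([[soma.gL + tc.gc, -tc.gc], [-tc.gc, tc.gLd + tc.gc]])
    V, Vd = np.linalg.solve(A, np.array([I + (soma.gL + tc.gc - tc.gc) * 0.0,
                                         0.0])) + soma.EL
    dV, _, dVd = two_compartment_derivatives((V, 0.0, Vd), tc, I)
    assert abs(dV) < 1e-6 and abs(dVd) < 1e-6
    assert V < Vd < soma.EL


def test_two_compartment_invariants(rep):
    with pytest.raises(ValueError):
        TwoCompartmentParams(soma=rep, gc=-1.0, Cd=100.0, gLd=1.0)
    with pytest.raises(ValueError):
        TwoCompartmentParams(soma=rep, gc=1.0, Cd=-5.0, gLd=1.0)


def test_params_validation():
    with pytest.raises(ValueError):
        it.AEIFParams(C=-1, gL=8, EL=-50, VT=-53, DeltaT=1, a=1, b=1,
                      tau_w=10, Vr=-60)
    with pytest.raises(ValueError):
        it.AEIFParams(C=100, gL=8, EL=-50, VT=-53, DeltaT=1, a=1, b=1,
                      tau_w=10, Vr=5.0)  # Vr above Vspike


def test_params_json_round_trip(rep, tmp_path):
    path = tmp_path / "p.json"
    rep.to_json(path)
    loaded = it.AEIFParams.from_json(path)
    assert loaded == rep
    d = json.loads(path.read_text())
    assert "C_pF" in d and "tau_w_ms" in d
    with pytest.raises(ValueError):
        it.AEIFParams.from_dict({"C": 100.0})  # unit suffix required


def test_rescaled_model_is_exactly_conjugate(rep):
    # integrating the dimensionless model with the transformed step and
    # initial condition reproduces the original spike count exactly
    import isrtools as it2
    I = 100.0  # suprathreshold constant input
    dt = 0.1
    n = int(1000.0 / dt)
    wf = it2.CurrentWaveform(dt=dt, samples=np.full(n, I))
    _, train, _ = it2.integrate(rep, wf, init=(rep.EL, 0.0), dt=dt,
                                record=False)

    rs = it2.rescale(rep, I)
    dtb = dt / rep.tau_m
    vb = (rep.EL - rep.VT) / rep.DeltaT
    wb = (0.0 + rep.a * (rep.EL - rep.VT)) / (rep.gL * rep.DeltaT)
    vspike_b = (rep.Vspike - rep.VT) / rep.DeltaT
    count = 0
    for _ in range(n):
        dv = -vb + math.exp(vb) - wb + rs.Ibar
        dw = (rs.A * vb - wb) / rs.T
        vb += dtb * dv
        wb += dtb * dw
        if vb > vspike_b:
            count += 1
            vb = rs.Vr_bar
            wb += rs.bbar
    assert count == len(train)
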