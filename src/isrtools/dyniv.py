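"""Parameter estimation from current-clamp traces (modified dynamic I-V).

The dynamic I-V method splits the injected current into capacitive and ionic
components, ``I_m = I_in - C dV/dt``, and averages ``I_m`` within voltage
bins to obtain the dynamic I-V curve ``I_dyn(V)``.  The stages are:

1. capacitance: ``C_e`` minimizes the count-weighted within-bin variance of
   ``I_in/C_e - dV/dt`` (the variance is smallest when the capacitive
   current is subtracted with the true capacitance);
2. the curve ``-I_dyn(V)/C`` is fitted with the EIF form
   ``F(V) = (E_L - V + Delta_T exp((V-V_T)/Delta_T))/tau_m``;
3. the membrane time constant is fitted to the relaxation after a brief
   current pulse (biexponential for a cell with a dendritic compartment);
4. the subthreshold adaptation conductance ``a`` is the slope of the linear
   part of the curve minus the leak conductance;
5. the spike-triggered adaptation ``w_spike = I_in - C dV/dt -
   (g_L + a)(V - E_L)`` is binned by time since the last spike and fitted
   with a single exponential (amplitude ``b``, time constant ``tau_w``).

These classical stages treat the adaptation current as if it followed the
voltage instantaneously.  For a neuron with slow, strong adaptation the
conditional mean E[w | V] is attenuated relative to ``a (V - E_L)`` (the
adaptation cannot track the 3-10 ms input fluctuations), which biases the
raw slope and everything derived from it.  ``fit_full`` therefore finishes
with a self-consistent refinement: the adaptation current is reconstructed
sample-by-sample from the measured voltage and spike times, and all
parameters are estimated by least squares on the current-balance residual,
alternating with an adaptation-corrected capacitance estimate.  The stage
estimates are kept in the fit report.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit, least_squares, minimize_scalar

from . import _kernels
from .params import AEIFParams
from .integrator import SpikeTrain, VoltageTrace
from .response import detect_spikes

__all__ = [
    "SpikeExclusion",
    "DynamicIVCurve",
    "EIFFit",
    "AdaptationFit",
    "PulseFit",
    "estimate_capacitance",
    "dynamic_iv_curve",
    "fit_eif",
    "fit_membrane_tau_pulse",
    "estimate_subthreshold_a",
    "fit_spike_adaptation",
    "refine_consistent",
    "fit_full",
]


@dataclass(frozen=True)
class SpikeExclusion:
    """Samples excluded around each spike (from peak to peak + post_ms)."""

    post_ms: float = 10.0
    pre_ms: float = 0.3

    def mask(self, n: int, dt: float, spike_idx: np.ndarray,
             settle_ms: float = 500.0) -> np.ndarray:
        """Boolean inclusion mask (True = keep)."""
        excl = np.zeros(n, bool)
        pre = int(self.pre_ms / dt)
        post = int(self.post_ms / dt)
        for s in spike_idx:
            excl[max(0, s - pre):min(n, s + post)] = True
        excl[: int(settle_ms / dt)] = True
        excl[0] = excl[-1] = True
        return ~excl


def _dVdt(V: np.ndarray, dt: float) -> np.ndarray:
    d = np.empty_like(V)
    d[1:-1] = (V[2:] - V[:-2]) / (2.0 * dt)
    d[0] = d[-1] = 0.0
    return d


def _spike_indices(trace: VoltageTrace, spikes: Optional[SpikeTrain]) -> np.ndarray:
    if spikes is None:
        spikes = detect_spikes(trace)
    return (spikes.times_ms / trace.dt).astype(np.int64)


def _bin_moments(V, x, y, idx, bin_mV, min_count):
    """Per-voltage-bin counts and first/second moments of (x, y)."""
    vb = np.floor(V[idx] / bin_mV).astype(np.int64)
    _, inv = np.unique(vb, return_inverse=True)
    cnt = np.bincount(inv).astype(float)
    sx = np.bincount(inv, weights=x[idx])
    sy = np.bincount(inv, weights=y[idx])
    sxx = np.bincount(inv, weights=x[idx] ** 2)
    syy = np.bincount(inv, weights=y[idx] ** 2)
    sxy = np.bincount(inv, weights=x[idx] * y[idx])
    ok = cnt >= min_count
    return tuple(arr[ok] for arr in (cnt, sx, sy, sxx, syy, sxy))


@dataclass
class CapacitanceEstimate:
    Ce: float
    bracket: Tuple[float, float]
    tol: float
    grid: np.ndarray
    objective: np.ndarray
    unimodal: bool


def estimate_capacitance(
    trace: VoltageTrace,
    bin_mV: float = 1.0,
    exclusion: SpikeExclusion = SpikeExclusion(),
    *,
    spikes: Optional[SpikeTrain] = None,
    bracket: Tuple[float, float] = (50.0, 600.0),
    grid_pF: float = 1.0,
    min_count: int = 50,
    tol: float = 0.01,
    w_estimate: Optional[np.ndarray] = None,
) -> CapacitanceEstimate:
    """Capacitance from the variance-minimization criterion.

    Minimizes the count-weighted sum over voltage bins of
    ``var(I_in/C_e - dV/dt)`` over ``C_e`` in ``bracket`` (coarse grid then
    golden-section refinement; a non-unimodal grid objective triggers a
    warning and the global grid minimum is used as the refinement center).
    ``w_estimate`` optionally subtracts a reconstructed adaptation current
    from ``I_in`` first (used by the self-consistent refinement).
    """
    spk = _spike_indices(trace, spikes)
    inc = exclusion.mask(trace.n, trace.dt, spk)
    idx = np.where(inc)[0]
    if len(idx) * trace.dt < 5000.0:
        raise ValueError("need >= 5 s of included subthreshold data")
    I = trace.I_in if w_estimate is None else trace.I_in - w_estimate
    d = _dVdt(trace.V, trace.dt)
    cnt, sI, sD, sII, sDD, sID = _bin_moments(trace.V, I, d, idx, bin_mV,
                                              min_count)
    varI = sII / cnt - (sI / cnt) ** 2
    covID = sID / cnt - sI * sD / cnt ** 2
    varD = sDD / cnt - (sD / cnt) ** 2

    def J(Ce: float) -> float:
        u = 1.0 / Ce
        return float(np.sum(cnt * (u * u * varI - 2.0 * u * covID + varD)))

    grid = np.arange(bracket[0], bracket[1] + grid_pF, grid_pF)
    vals = np.array([J(c) for c in grid])
    k = int(np.argmin(vals))
    interior = vals[1:-1]
    n_min = int(np.sum((interior < vals[:-2]) & (interior <= vals[2:])))
    unimodal = n_min <= 1
    if not unimodal:
        warnings.warn("capacitance objective is not unimodal over the "
                      "bracket; using global grid minimum", stacklevel=2)
    lo = grid[max(0, k - 2)]
    hi = grid[min(len(grid) - 1, k + 2)]
    res = minimize_scalar(J, bounds=(lo, hi), method="bounded",
                          options={"xatol": tol})
    return CapacitanceEstimate(Ce=float(res.x), bracket=bracket, tol=tol,
                               grid=grid, objective=vals, unimodal=unimodal)


@dataclass
class DynamicIVCurve:
    """Binned dynamic I-V curve: per-bin mean ionic current vs voltage."""

    V: np.ndarray          # bin centers, mV
    I_dyn: np.ndarray      # mean I_m per bin, pA
    sd: np.ndarray
    count: np.ndarray
    Ce: float


def dynamic_iv_curve(
    trace: VoltageTrace,
    Ce: float,
    bin_mV: float = 1.0,
    exclusion: SpikeExclusion = SpikeExclusion(),
    *,
    spikes: Optional[SpikeTrain] = None,
    min_count: int = 50,
    V_max: float = -40.0,
    w_estimate: Optional[np.ndarray] = None,
) -> DynamicIVCurve:
    """Average of ``I_m = I_in - Ce dV/dt`` within voltage bins.

    Samples inside exclusion windows and above ``V_max`` (spike upstroke) are
    dropped; bins with fewer than ``min_count`` samples are omitted.
    """
    if Ce <= 0:
        raise ValueError("Ce must be > 0")
    spk = _spike_indices(trace, spikes)
    inc = exclusion.mask(trace.n, trace.dt, spk)
    Im = trace.I_in - Ce * _dVdt(trace.V, trace.dt)
    if w_estimate is not None:
        Im = Im - w_estimate
    idx = np.where(inc & (trace.V < V_max))[0]
    vb = np.floor(trace.V[idx] / bin_mV).astype(np.int64)
    uniq, inv = np.unique(vb, return_inverse=True)
    cnt = np.bincount(inv).astype(float)
    s1 = np.bincount(inv, weights=Im[idx])
    s2 = np.bincount(inv, weights=Im[idx] ** 2)
    mean = s1 / cnt
    sd = np.sqrt(np.maximum(s2 / cnt - mean ** 2, 0.0))
    ok = cnt >= min_count
    centers = (uniq + 0.5) * bin_mV
    return DynamicIVCurve(V=centers[ok], I_dyn=mean[ok], sd=sd[ok],
                          count=cnt[ok], Ce=Ce)


@dataclass
class EIFFit:
    """EIF parameters fitted to -I_dyn(V)/C."""

    tau_m_dyn: float
    EL: float
    VT: float
    DeltaT: float
    Ce: float
    residual: float

    @property
    def slope_nS(self) -> float:
        """Total linear conductance implied by the fit, C/tau_m_dyn."""
        return self.Ce / self.tau_m_dyn


def _F_eif(V, tau_m, EL, VT, DT):
    return (EL - V + DT * np.exp(np.minimum((V - VT) / DT, 30.0))) / tau_m


def fit_eif(curve: DynamicIVCurve) -> EIFFit:
    """Weighted nonlinear least squares of F(V) = -I_dyn/C to the EIF form."""
    F = -curve.I_dyn / curve.Ce
    wgt = curve.sd / curve.Ce / np.sqrt(curve.count)
    wgt = np.where(wgt > 0, wgt, np.median(wgt[wgt > 0]) if
                   np.any(wgt > 0) else 1.0)
    span = curve.V.max() - curve.V.min()
    if span < 8.0:
        raise ValueError("curve spans too little voltage for an EIF fit")
    p0 = [10.0, curve.V.mean(), curve.V.max() - 2.0, 1.0]
    try:
        popt, pcov = curve_fit(
            _F_eif, curve.V, F, p0=p0, sigma=wgt, maxfev=40000,
            bounds=([0.1, -90.0, -75.0, 0.1], [500.0, -30.0, -35.0, 8.0]))
    except RuntimeError as err:
        raise RuntimeError(f"EIF fit did not converge: {err}") from err
    resid = float(np.sum(((_F_eif(curve.V, *popt) - F) / wgt) ** 2))
    return EIFFit(tau_m_dyn=float(popt[0]), EL=float(popt[1]),
                  VT=float(popt[2]), DeltaT=float(popt[3]), Ce=curve.Ce,
                  residual=resid)


@dataclass
class PulseFit:
    """Membrane time constants from the decay after a brief current pulse."""

    tau_m: float                # slow constant, ms
    tau_c: float                # fast constant, ms (0 if single-exponential)
    amplitudes: Tuple[float, float]
    mode: str                   # biexp | single | damped_osc
    alpha: float = math.nan     # decay rate (1/ms) in damped_osc mode
    omega: float = math.nan     # angular frequency (rad/ms) in damped_osc mode

    def gL(self, C: float) -> float:
        """Leak conductance implied by C and the slow constant."""
        return C / self.tau_m


def fit_membrane_tau_pulse(trace: VoltageTrace,
                           fit_ms: float = 150.0,
                           delay_ms: float = 0.5) -> PulseFit:
    """Fit the relaxation after a short (0.5 ms) current pulse.

    Tries a biexponential ``V = V_inf + A1 e^{-t/tau_m} + A2 e^{-t/tau_c}``
    (tau_m > tau_c); if the two constants are degenerate (within 10%) a
    warning is issued.  When the relaxation is oscillatory (a focus rest
    state, as for strong subthreshold adaptation) the biexponential cannot
    represent it and a damped cosine
    ``V = V_inf + e^{-alpha t}(P cos omega t + Q sin omega t)`` is fitted
    instead (mode="damped_osc"; alpha plays the role of the mean decay rate).
    """
    dI = np.abs(np.diff(trace.I_in))
    i_pulse = int(np.argmax(dI))
    # end of pulse: last large current step within 5 ms of the first
    win = int(5.0 / trace.dt)
    seg = dI[i_pulse:i_pulse + win]
    i_end = i_pulse + np.where(seg > 0.5 * seg.max())[0][-1] + 1
    i0 = i_end + int(delay_ms / trace.dt)
    i1 = min(trace.n, i0 + int(fit_ms / trace.dt))
    if (i1 - i0) * trace.dt < 50.0:
        raise ValueError("need >= 50 ms of post-pulse decay")
    t = (np.arange(i1 - i0)) * trace.dt
    v = trace.V[i0:i1]
    v_inf = v[-max(5, len(v) // 20):].mean()

    def biexp(tt, vi, a1, tm, a2, tc):
        return vi + a1 * np.exp(-tt / tm) + a2 * np.exp(-tt / tc)

    amp0 = v[0] - v_inf
    try:
        popt, _ = curve_fit(
            biexp, t, v, p0=[v_inf, 0.8 * amp0, 20.0, 0.2 * amp0, 2.0],
            maxfev=40000,
            bounds=([-90, -60, 0.5, -60, 0.05], [0, 60, 500.0, 60, 400.0]))
        vi, a1, tm, a2, tc = popt
        if tm < tc:
            a1, a2, tm, tc = a2, a1, tc, tm
        pred = biexp(t, vi, a1, tm, a2, tc)
        r2 = 1.0 - np.var(v - pred) / max(np.var(v), 1e-12)
        if r2 > 0.98:
            if tc > 0.9 * tm:
                warnings.warn("pulse fit is degenerate: tau_m ~ tau_c",
                              stacklevel=2)
            if abs(a2) < 0.02 * abs(a1):
                return PulseFit(tau_m=float(tm), tau_c=0.0,
                                amplitudes=(float(a1), float(a2)),
                                mode="single")
            return PulseFit(tau_m=float(tm), tau_c=float(tc),
                            amplitudes=(float(a1), float(a2)), mode="biexp")
    except RuntimeError:
        pass

    def damped(tt, vi, P, Q, alpha, omega):
        return vi + np.exp(-alpha * tt) * (P * np.cos(omega * tt)
                                           + Q * np.sin(omega * tt))

    popt, _ = curve_fit(
        damped, t, v, p0=[v_inf, amp0, 0.0, 0.05, 0.08], maxfev=40000,
        bounds=([-90, -60, -60, 1e-4, 1e-3], [0, 60, 60, 2.0, 2.0]))
    vi, P, Q, alpha, omega = popt
    return PulseFit(tau_m=float(1.0 / alpha), tau_c=float(1.0 / alpha),
                    amplitudes=(float(P), float(Q)), mode="damped_osc",
                    alpha=float(alpha), omega=float(omega))


def estimate_subthreshold_a(
    curve: DynamicIVCurve,
    gL: float,
    window: Optional[Tuple[float, float]] = None,
) -> float:
    """Subthreshold adaptation conductance: linear I-V slope minus leak.

    The window defaults to [EL - 10 mV, VT - 3 DeltaT] from an EIF fit of the
    curve, staying clear of the exponential region.  Note that when the
    adaptation is slower than the input fluctuations the slope of the
    *conditional mean* underestimates ``gL + a`` (see module docstring);
    ``fit_full``'s refinement corrects this.
    """
    if window is None:
        e = fit_eif(curve)
        window = (e.EL - 10.0, e.VT - 3.0 * e.DeltaT)
    m = (curve.V >= window[0]) & (curve.V <= window[1])
    if m.sum() < 5:
        raise ValueError(
            f"fewer than 5 bins inside linear window {window}")
    slope = np.polyfit(curve.V[m], curve.I_dyn[m], 1,
                       w=np.sqrt(curve.count[m]))[0]
    return float(slope - gL)


@dataclass
class AdaptationFit:
    """Spike-triggered adaptation: single-exponential fit of w_spike(t)."""

    a: float
    b: float
    tau_w: float
    residual: float
    window_ms: Tuple[float, float]
    t_ms: np.ndarray = field(default_factory=lambda: np.array([]))
    w_mean: np.ndarray = field(default_factory=lambda: np.array([]))


def fit_spike_adaptation(
    trace: VoltageTrace,
    Ce: float,
    gL: float,
    a: float,
    EL: float,
    exclusion: SpikeExclusion = SpikeExclusion(),
    *,
    spikes: Optional[SpikeTrain] = None,
    window_ms: Tuple[float, float] = (5.0, 100.0),
    bin_ms: float = 2.0,
    VT_cut: Optional[float] = None,
) -> AdaptationFit:
    """w_spike per sample, binned by time since the last spike, exp-fitted.

    ``w_spike = I_in - Ce dV/dt - (gL + a)(V - EL)`` (valid far from
    threshold; samples above ``VT_cut`` are dropped).  The binned means are
    fitted with ``b exp(-t/tau_w)``; b is the extrapolated value at t = 0.
    """
    spk = _spike_indices(trace, spikes)
    if len(spk) < 100:
        raise ValueError("need >= 100 spikes for the adaptation fit")
    n = trace.n
    t = np.arange(n) * trace.dt
    last = np.full(n, -np.inf)
    prev = -np.inf
    si = 0
    for i in range(n):
        if si < len(spk) and spk[si] == i:
            prev = t[i]
            si += 1
        last[i] = t[i] - prev
    wsp = trace.I_in - Ce * _dVdt(trace.V, trace.dt) \
        - (gL + a) * (trace.V - EL)
    if VT_cut is None:
        VT_cut = np.quantile(trace.V, 0.9)
    m = (last >= window_ms[0]) & (last <= window_ms[1]) & (trace.V < VT_cut)
    m &= np.isfinite(last)
    tb = np.floor(last[m] / bin_ms).astype(int)
    cnt = np.bincount(tb)
    s1 = np.bincount(tb, weights=wsp[m])
    ok = cnt >= 30
    tc = (np.arange(len(cnt)) + 0.5) * bin_ms
    tc, mw = tc[ok], (s1 / np.maximum(cnt, 1))[ok]
    if tc.max() - tc.min() < 3.0 * bin_ms:
        raise ValueError("insufficient post-spike time coverage")
    popt, _ = curve_fit(lambda tt, bb, tw: bb * np.exp(-tt / tw), tc, mw,
                        p0=[max(mw[0], 50.0), 20.0], maxfev=40000,
                        bounds=([0.0, 1.0], [5000.0, 500.0]))
    b, tw = popt
    if tc.max() < 3.0 * tw:
        warnings.warn("post-spike coverage < 3 tau_w; tau_w poorly "
                      "constrained", stacklevel=2)
    resid = float(np.sqrt(np.mean((mw - b * np.exp(-tc / tw)) ** 2)))
    return AdaptationFit(a=a, b=float(b), tau_w=float(tw), residual=resid,
                         window_ms=window_ms, t_ms=tc, w_mean=mw)


def refine_consistent(
    trace: VoltageTrace,
    Ce0: float,
    init: Sequence[float],
    exclusion: SpikeExclusion = SpikeExclusion(),
    *,
    spikes: Optional[SpikeTrain] = None,
    iters: int = 4,
    subsample: int = 2,
    V_fit_max: float = -48.0,
) -> Tuple[float, np.ndarray]:
    """Self-consistent refinement of (gL, EL, VT, DeltaT, a, tau_w, b) and C.

    Alternates (i) least squares of the full current balance
    ``I_in - C dV/dt = gL (V-EL) - gL DT e^{(V-VT)/DT} + w(t)`` with the
    adaptation current ``w(t)`` reconstructed from the measured voltage and
    spike times, and (ii) re-estimation of C with the variance criterion
    applied to ``I_in - w(t)``.  Raw (unfiltered) signals are used throughout:
    the differentiation noise is independent of the regressors and averages
    out, whereas low-pass filtering biases the exponential term.
    """
    spk = _spike_indices(trace, spikes)
    inc = exclusion.mask(trace.n, trace.dt, spk)
    V = trace.V
    I = trace.I_in
    dt = trace.dt
    d = _dVdt(V, dt)
    fitm = inc & (V < V_fit_max)
    sel = np.where(fitm)[0][::subsample]
    lb = np.array([0.5, -80.0, -70.0, 0.2, 0.0, 2.0, 0.0])
    ub = np.array([300.0, -40.0, -45.0, 6.0, 300.0, 200.0, 3000.0])
    th = np.clip(np.asarray(init, dtype=float), lb, ub)
    Ce = Ce0

    def solve(start, y):
        def resid(t7):
            g, el, vt, dtl, aa, twl, bb = t7
            w = _kernels.reconstruct_w(V, dt, spk, el, aa, twl, bb, 0.0)
            pred = g * (V - el) - g * dtl * np.exp(
                np.minimum((V - vt) / dtl, 30.0)) + w
            return (y - pred)[sel]

        sol = least_squares(resid, start, bounds=(lb, ub),
                            x_scale=[10, 5, 5, 0.5, 10, 10, 100])
        return sol.x, float(sol.cost)

    def curve_score(t7, Ce_c):
        # residual of the adaptation-corrected bin-mean I-V curve against
        # the fitted EIF form; bin means average out the differentiation
        # noise, so scores are comparable across capacitance candidates
        g, el, vt, dtl, aa, twl, bb = t7
        w = _kernels.reconstruct_w(V, dt, spk, el, aa, twl, bb, 0.0)
        y = I - Ce_c * d - w
        idx = np.where(inc & (V < V_fit_max + 3.0))[0]
        vb = np.floor(V[idx]).astype(np.int64)
        _, inv = np.unique(vb, return_inverse=True)
        cnt = np.bincount(inv)
        mb = np.bincount(inv, weights=y[idx]) / cnt
        vm = np.bincount(inv, weights=V[idx]) / cnt
        ok = cnt >= 200
        G = g * (vm - el) - g * dtl * np.exp(
            np.minimum((vm - vt) / dtl, 30.0))
        return float(np.sum(cnt[ok] * (mb[ok] - G[ok]) ** 2)
                     / np.sum(cnt[ok]))

    # stage 1: multi-start over the adaptation timescale at the raw Ce
    # (the least-identifiable direction: spike exclusion hides the early
    # post-spike decay)
    y0 = I - Ce * d
    starts = [th]
    for tw0 in (5.0, 10.0, 20.0):
        alt = th.copy()
        alt[5] = tw0
        starts.append(np.clip(alt, lb, ub))
    sols = [solve(s, y0) for s in starts]
    th = min(sols, key=lambda sc: sc[1])[0]
    candidates = [(th, Ce)]
    # stage 2: alternate with the adaptation-corrected capacitance; every
    # intermediate is kept as a candidate because the alternation has no
    # joint objective and can drift for cells with fast adaptation
    for _ in range(max(iters - 1, 1)):
        w = _kernels.reconstruct_w(V, dt, spk, th[1], th[4], th[5], th[6],
                                   0.0)
        Ce = estimate_capacitance(trace, exclusion=exclusion, spikes=_ST(
            spk, trace), w_estimate=w).Ce
        th = solve(th, I - Ce * d)[0]
        candidates.append((th, Ce))
    th, Ce = min(candidates, key=lambda c: curve_score(*c))
    return float(Ce), np.asarray(th)


def _ST(spk_idx: np.ndarray, trace: VoltageTrace) -> SpikeTrain:
    return SpikeTrain(spk_idx * trace.dt, trace.duration_ms)


def fit_full(
    noise_trace: VoltageTrace,
    pulse_trace: Optional[VoltageTrace] = None,
    *,
    exclusion: SpikeExclusion = SpikeExclusion(),
    Vspike: float = 0.0,
    refine: bool = True,
) -> Tuple[AEIFParams, dict]:
    """Complete aEIF parameter fit from a noise and an optional pulse trace.

    Runs capacitance -> dynamic I-V curve -> EIF fit -> pulse tau_m ->
    subthreshold a -> spike-triggered adaptation, then (default) the
    self-consistent refinement that the staged estimators initialize.  The
    returned parameters are the refined ones; the report carries every stage.
    The voltage reset Vr is estimated as the median voltage one sample after
    each spike.
    """
    report: dict = {}
    spikes = detect_spikes(noise_trace)
    spk_idx = (spikes.times_ms / noise_trace.dt).astype(np.int64)
    report["n_spikes"] = len(spikes)

    cap = estimate_capacitance(noise_trace, exclusion=exclusion,
                               spikes=spikes)
    report["capacitance"] = cap
    curve = dynamic_iv_curve(noise_trace, cap.Ce, exclusion=exclusion,
                             spikes=spikes)
    report["iv_curve"] = curve
    eif = fit_eif(curve)
    report["eif"] = eif

    pulse = None
    if pulse_trace is not None:
        pulse = fit_membrane_tau_pulse(pulse_trace)
        report["pulse"] = pulse
        gL_stage = pulse.gL(cap.Ce) if pulse.mode != "damped_osc" else \
            0.5 * eif.slope_nS
    else:
        warnings.warn("no pulse trace given; falling back to the dynamic-IV "
                      "time constant for the leak estimate", stacklevel=2)
        gL_stage = eif.slope_nS * 0.5
    report["gL_stage"] = gL_stage

    try:
        a_stage = estimate_subthreshold_a(curve, gL_stage)
    except (ValueError, RuntimeError):
        a_stage = max(eif.slope_nS - gL_stage, 0.0)
    report["a_stage"] = a_stage

    adapt = fit_spike_adaptation(
        noise_trace, cap.Ce, gL_stage, a_stage, eif.EL,
        exclusion=exclusion, spikes=spikes, VT_cut=eif.VT - 2.0 * eif.DeltaT)
    report["adaptation"] = adapt

    # voltage reset from the sample following each spike
    after = np.minimum(spk_idx + 1, noise_trace.n - 1)
    Vr = float(np.median(noise_trace.V[after]))
    report["Vr"] = Vr

    if refine:
        init = [gL_stage, eif.EL, eif.VT, eif.DeltaT,
                max(a_stage, 5.0), adapt.tau_w, adapt.b]
        Ce, th = refine_consistent(noise_trace, cap.Ce, init,
                                   exclusion=exclusion, spikes=spikes)
        report["refined"] = {"C": Ce, "theta": th}
        g, el, vt, dtl, aa, twl, bb = th
        params = AEIFParams(C=Ce, gL=g, EL=el, VT=vt, DeltaT=dtl, a=aa,
                            b=bb, tau_w=twl, Vr=min(Vr, vt - 1.0),
                            Vspike=Vspike)
    else:
        params = AEIFParams(C=cap.Ce, gL=gL_stage, EL=eif.EL, VT=eif.VT,
                            DeltaT=eif.DeltaT, a=max(a_stage, 0.0),
                            b=adapt.b, tau_w=adapt.tau_w,
                            Vr=min(Vr, eif.VT - 1.0), Vspike=Vspike)
    return params, report
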