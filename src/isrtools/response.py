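"""Protocol-level response statistics.

Implements the analyses applied to both recorded and simulated Purkinje-cell
activity: spike detection, firing-rate-vs-noise-amplitude (ISR) curves for
stepped and continuously ramped noise, ramp hysteresis (Delta f, Delta I),
f-I curves, peristimulus time histograms of the spiking-state probability,
decay time constants of stimulus-evoked firing, input-output curves and
membrane-potential histograms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit

from . import _kernels
from .params import AEIFParams
from .stimulus import (BiexpInputSpec, CurrentWaveform, OUSpec, biexp_current,
                       build_protocol, ou_series)
from .integrator import (SpikeTrain, VoltageTrace, _ptuple, integrate,
                         limit_cycle_state, rest_state)
from .phaseplane import BasinMask, rest_basin

__all__ = [
    "ISRCurve",
    "HysteresisResult",
    "PSTHResult",
    "detect_spikes",
    "isr_curve",
    "isr_curve_from_model",
    "isr_curve_continuous",
    "hysteresis_ramp",
    "fi_curve",
    "psth",
    "decay_time_constant",
    "input_output_curve",
    "vm_histogram",
]


def detect_spikes(trace: VoltageTrace, threshold: float = -20.0,
                  refractory_ms: float = 2.0) -> SpikeTrain:
    """Upward threshold crossings with refractory enforcement."""
    V = trace.V
    up = np.where((V[1:] > threshold) & (V[:-1] <= threshold))[0] + 1
    times = up * trace.dt
    kept: List[float] = []
    last = -math.inf
    for t in times:
        if t - last >= refractory_ms:
            kept.append(t)
            last = t
    return SpikeTrain(np.asarray(kept), trace.duration_ms)


@dataclass
class ISRCurve:
    """Firing rate vs noise amplitude with its (smoothed) minimum."""

    sigma: np.ndarray
    rate: np.ndarray          # Hz, mean over epochs per sigma
    rate_sd: np.ndarray
    smoothed: np.ndarray
    smoothing_pA: float
    sigma_opt: float
    flat: bool = False        # True if the curve has no meaningful minimum


def isr_curve(
    epochs: Sequence[Tuple[float, int, float]],
    smoothing_pA: Optional[float] = None,
) -> ISRCurve:
    """ISR curve from per-epoch (sigma, spike count, duration_ms) triples.

    The per-sigma mean rate is smoothed with a Gaussian filter whose width
    defaults to the sigma step size; sigma_opt is the argmin of the smoothed
    curve.  A flat curve (peak-to-peak below twice the mean across-epoch
    standard error) is flagged.
    """
    sig = np.asarray([e[0] for e in epochs], dtype=float)
    rates = np.asarray([e[1] / (e[2] / 1000.0) for e in epochs])
    grid = np.unique(sig)
    if len(grid) < 3:
        raise ValueError("need at least 3 distinct noise amplitudes")
    mean = np.array([rates[sig == s].mean() for s in grid])
    sd = np.array([rates[sig == s].std() for s in grid])
    nrep = np.array([(sig == s).sum() for s in grid])
    step = float(np.median(np.diff(grid)))
    if smoothing_pA is None:
        smoothing_pA = step
    sm = gaussian_filter1d(mean, sigma=smoothing_pA / step, mode="nearest",
                           truncate=3.0)
    sem = sd / np.sqrt(np.maximum(nrep, 1))
    flat = bool(sm.max() - sm.min() <= max(2.0 * sem.mean(), 1e-9))
    if flat:
        warnings.warn("ISR curve is flat; sigma_opt is not significant",
                      stacklevel=2)
    return ISRCurve(sigma=grid, rate=mean, rate_sd=sd, smoothed=sm,
                    smoothing_pA=smoothing_pA,
                    sigma_opt=float(grid[int(np.argmin(sm))]), flat=flat)


def isr_curve_from_model(
    params: AEIFParams,
    I_mean: float,
    sigmas: Sequence[float],
    reps: int = 20,
    T_ms: float = 30_000.0,
    seed: int = 0,
    *,
    tau_noise: float = 2.0,
    dt: float = 0.1,
    init: str = "limit_cycle",
    smoothing_pA: Optional[float] = None,
) -> ISRCurve:
    """Simulate the stepped-noise ISR protocol on the model.

    For each noise amplitude, ``reps`` independent epochs of ``T_ms`` are
    integrated (initialized on the noise-free limit cycle, i.e. in the firing
    state) and the mean firing rate is taken.
    """
    if init == "limit_cycle":
        from .phaseplane import limit_cycle_state_or_fallback
        V0, w0 = limit_cycle_state_or_fallback(params, I_mean)
    else:
        V0, w0 = rest_state(params, I_mean, dt=dt)
    n = int(T_ms / dt)
    epochs = []
    for k, s in enumerate(sigmas):
        for r in range(reps):
            wf = ou_series(OUSpec(mu=I_mean, sigma=float(s), tau=tau_noise),
                           dt, n, seed=seed * 1_000_003 + k * 1_009 + r)
            spk, _, _ = _kernels.aeif_spikes(*_ptuple(params), wf.samples,
                                             dt, V0, w0)
            epochs.append((float(s), len(spk), T_ms))
    return isr_curve(epochs, smoothing_pA=smoothing_pA)


def isr_curve_continuous(
    trace: VoltageTrace,
    sigma_samples: Optional[np.ndarray] = None,
    window_ms: float = 200.0,
    bin_pA: float = 20.0,
    threshold: float = -20.0,
) -> Tuple[ISRCurve, ISRCurve]:
    """History-resolved ISR curves from a continuously ramped noise protocol.

    The trace is cut into ``window_ms`` windows labeled by the firing state of
    the *previous* window; per label, window firing rates are averaged within
    ``bin_pA`` bins of the per-sample noise amplitude.  Returns
    (was_firing, was_silent) curves; an empty category yields a curve with
    empty arrays.
    """
    if sigma_samples is None:
        sigma_samples = trace.meta.get("sigma_samples")
    if sigma_samples is None:
        raise ValueError("per-sample noise amplitude annotation required")
    sigma_samples = np.asarray(sigma_samples)
    if len(sigma_samples) != trace.n:
        raise ValueError("sigma annotation length mismatch")
    spikes = detect_spikes(trace, threshold=threshold)
    nw = int(window_ms / trace.dt)
    n_win = trace.n // nw
    counts = np.zeros(n_win)
    if len(spikes):
        wi = (spikes.times_ms / window_ms).astype(int)
        wi = wi[wi < n_win]
        np.add.at(counts, wi, 1)
    rates = counts / (window_ms / 1000.0)
    sig_win = np.array([sigma_samples[k * nw:(k + 1) * nw].mean()
                        for k in range(n_win)])
    prev_firing = np.concatenate([[False], counts[:-1] > 0])

    def running(label_mask: np.ndarray) -> ISRCurve:
        r = rates[label_mask]
        s = sig_win[label_mask]
        if len(s) == 0:
            z = np.array([])
            return ISRCurve(z, z, z, z, bin_pA, math.nan, flat=True)
        edges = np.arange(0.0, s.max() + bin_pA, bin_pA)
        centers, mean, sd = [], [], []
        for lo in edges[:-1]:
            m = (s >= lo) & (s < lo + bin_pA)
            if m.sum() >= 2:
                centers.append(lo + bin_pA / 2)
                mean.append(r[m].mean())
                sd.append(r[m].std())
        centers = np.asarray(centers)
        mean = np.asarray(mean)
        sd = np.asarray(sd)
        if len(centers) == 0:
            z = np.array([])
            return ISRCurve(z, z, z, z, bin_pA, math.nan, flat=True)
        sm = gaussian_filter1d(mean, sigma=1.0, mode="nearest")
        return ISRCurve(centers, mean, sd, sm, bin_pA,
                        float(centers[int(np.argmin(sm))]),
                        flat=bool(sm.max() - sm.min() < 1e-9))

    return running(prev_firing), running(~prev_firing)


@dataclass
class HysteresisResult:
    """Ramp hysteresis summary (means over trials; NaN if a limb is silent)."""

    f_up: float
    f_down: float
    I_up: float
    I_down: float
    per_trial: dict = field(default_factory=dict)

    @property
    def delta_f(self) -> float:
        return self.f_up - self.f_down

    @property
    def delta_I(self) -> float:
        return self.I_up - self.I_down


def hysteresis_ramp(
    params: AEIFParams,
    rate_pA_per_ms: float = 0.9,
    trials: int = 10,
    I_start: float = -650.0,
    up_ms: float = 1000.0,
    dt: float = 0.1,
) -> HysteresisResult:
    """Symmetric-ramp hysteresis of the model (noise-free).

    Per trial: instantaneous frequency (reciprocal of the surrounding ISI) and
    instantaneous current of the first ascending and last descending spike.
    The first ascending spike has no preceding ISI, so its frequency uses the
    ISI to the second spike.
    """
    proto = build_protocol("ramp", dt=dt, I_start=I_start,
                           rate_pA_per_ms=rate_pA_per_ms, up_ms=up_ms,
                           trials=trials)
    _, train, _ = integrate(params, proto, init=(params.EL, 0.0), dt=dt,
                            record=False)
    I = proto.samples
    n_half = int(up_ms / dt)
    fu, fd, iu, idn = [], [], [], []
    for k in range(trials):
        t0 = 2 * k * n_half * dt
        t1 = t0 + up_ms
        t2 = t1 + up_ms
        ts = train.times_ms
        asc = ts[(ts >= t0) & (ts < t1)]
        dsc = ts[(ts >= t1) & (ts < t2)]
        limb = np.concatenate([asc, dsc])
        if len(asc) >= 1:
            iu.append(I[int(asc[0] / dt)])
            if len(limb) >= 2:
                fu.append(1000.0 / (limb[1] - limb[0]))
        if len(dsc) >= 1:
            idn.append(I[min(int(dsc[-1] / dt), len(I) - 1)])
            if len(limb) >= 2:
                fd.append(1000.0 / (limb[-1] - limb[-2]))
    def _m(x):
        return float(np.mean(x)) if x else math.nan
    return HysteresisResult(
        f_up=_m(fu), f_down=_m(fd), I_up=_m(iu), I_down=_m(idn),
        per_trial={"f_up": np.asarray(fu), "f_down": np.asarray(fd),
                   "I_up": np.asarray(iu), "I_down": np.asarray(idn)},
    )


def fi_curve(
    params: AEIFParams,
    I_start: float = -650.0,
    n_steps: int = 30,
    dI: float = 50.0,
    step_ms: float = 1000.0,
    dt: float = 0.1,
) -> dict:
    """f-I curve from a series of 1 s current steps.

    Returns a dict with arrays ``I`` (pA) and ``f`` (Hz), the onset current
    and the onset discontinuity (minimal nonzero firing frequency).
    """
    proto = build_protocol("current_steps", dt=dt, I_start=I_start,
                           n_steps=n_steps, dI=dI, step_ms=step_ms)
    _, train, _ = integrate(params, proto, init=(params.EL, 0.0), dt=dt,
                            record=False)
    ns = int(step_ms / dt)
    Is = I_start + dI * np.arange(n_steps)
    f = np.zeros(n_steps)
    if len(train):
        ks = (train.times_ms / step_ms).astype(int)
        ks = ks[ks < n_steps]
        np.add.at(f, ks, 1)
    f /= step_ms / 1000.0
    nz = np.where(f > 0)[0]
    onset_I = float(Is[nz[0]]) if len(nz) else math.nan
    f_min = float(f[nz[0]]) if len(nz) else math.nan
    return {"I": Is, "f": f, "onset_I": onset_I, "f_min_onset": f_min}


@dataclass
class PSTHResult:
    """Per-bin spiking probability across sweeps, stimulus-aligned.

    ``p`` is the reported probability (basin-state occupancy by default),
    ``p_spike`` the fraction of sweeps with >= 1 spike in the bin.
    """

    bin_edges_ms: np.ndarray
    p: np.ndarray
    p_spike: np.ndarray
    sweeps: int
    t_st_ms: float
    baseline: float
    mode: str

    @property
    def t_centers_ms(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:])


def psth(
    params: AEIFParams,
    Am: float,
    sigma: float,
    sweeps: int = 1000,
    T_ms: float = 6000.0,
    bin_ms: float = 20.0,
    seed: int = 0,
    *,
    I_mean: float = -150.0,
    t_st_ms: float = 3000.0,
    tau_noise: float = 2.0,
    dt: float = 0.1,
    basin: Optional[BasinMask] = None,
    probability: str = "basin",
    baseline_window_ms: float = 2000.0,
) -> PSTHResult:
    """Peristimulus time histogram of the spiking-state probability.

    Each sweep starts in the rest state and receives OU noise plus one
    biexponential excitatory event of amplitude ``Am`` at ``t_st_ms``.  With
    ``probability="basin"`` (default) the per-bin probability is the mean
    fraction of the bin spent outside the rest basin (the occupancy
    probability P_sp = 1 - P_r evaluated per bin); ``probability="spike"`` reports the
    fraction of sweeps with at least one spike in the bin.
    """
    if probability not in ("basin", "spike"):
        raise ValueError("probability must be 'basin' or 'spike'")
    if basin is None:
        basin = rest_basin(params, I_mean)
    V0, w0 = basin.fixed_point.V, basin.fixed_point.w
    n = int(T_ms / dt)
    binsteps = int(bin_ms / dt)
    nb = n // binsteps
    syn = np.zeros(n)
    if Am != 0.0:
        syn = biexp_current(BiexpInputSpec((t_st_ms,), Am), dt, n).samples
    acc_basin = np.zeros(nb)
    acc_spike = np.zeros(nb)
    for k in range(sweeps):
        wf = ou_series(OUSpec(mu=I_mean, sigma=sigma, tau=tau_noise), dt, n,
                       seed=seed * 2_000_003 + k)
        out, spk_bin, _ = _kernels.aeif_occupancy(
            *_ptuple(params), wf.samples + syn, dt, V0, w0,
            basin.mask, basin.Vg[0], basin.dv, basin.wg[0], basin.dw,
            binsteps)
        acc_basin += out
        acc_spike += spk_bin
    p_basin = acc_basin / sweeps
    p_spike = acc_spike / sweeps
    p = p_basin if probability == "basin" else p_spike
    edges = np.arange(nb + 1) * bin_ms
    base_lo = max(0.0, t_st_ms - baseline_window_ms)
    bsel = (edges[:-1] >= base_lo) & (edges[1:] <= t_st_ms)
    baseline = float(p[bsel].mean()) if bsel.any() else float(p.mean())
    return PSTHResult(bin_edges_ms=edges, p=p, p_spike=p_spike, sweeps=sweeps,
                      t_st_ms=t_st_ms, baseline=baseline, mode=probability)


def decay_time_constant(result: PSTHResult,
                        fit_window_ms: Optional[float] = None) -> dict:
    """Exponential decay constant of the post-stimulus PSTH.

    Fits ``P(t) = P_inf + (P0 - P_inf) exp(-(t - t_peak)/tau)`` over the
    post-peak window.  Returns tau in seconds with a 95% CI half-width; a
    PSTH that does not decay toward baseline (noise-free regime) is flagged
    infinite.
    """
    t = result.t_centers_ms
    post = t >= result.t_st_ms
    if not post.any():
        raise ValueError("no post-stimulus bins")
    tp = t[post]
    pp = result.p[post]
    k_peak = int(np.argmax(pp))
    p_peak = pp[k_peak]
    if p_peak <= result.baseline + 0.05:
        raise ValueError("post-stimulus probability does not exceed baseline")
    tp = tp[k_peak:]
    pp = pp[k_peak:]
    if fit_window_ms is not None:
        m = tp - tp[0] <= fit_window_ms
        tp, pp = tp[m], pp[m]
    # non-decaying latch: tail stays at peak level
    tail = pp[-max(3, len(pp) // 10):].mean()
    if tail > result.baseline + 0.8 * (p_peak - result.baseline):
        return {"tau_s": math.inf, "ci_s": math.nan, "infinite": True}

    def f(x, p_inf, p0, tau):
        return p_inf + (p0 - p_inf) * np.exp(-x / tau)

    x = (tp - tp[0]) / 1000.0
    popt, pcov = curve_fit(
        f, x, pp, p0=[result.baseline, p_peak, 1.0],
        bounds=([0.0, 0.0, 1e-3], [1.0, 1.5, 1e3]), maxfev=20000)
    tau = float(popt[2])
    ci = 1.96 * float(np.sqrt(np.abs(pcov[2, 2])))
    return {"tau_s": tau, "ci_s": ci, "infinite": False,
            "p_inf": float(popt[0]), "p0": float(popt[1])}


def input_output_curve(
    params: AEIFParams,
    sigma: float,
    amplitudes: Sequence[float],
    sweeps: int = 500,
    seed: int = 0,
    *,
    I_mean: float = -150.0,
    threshold_excess: float = 0.1,
    saturation_frac: float = 0.05,
    basin: Optional[BasinMask] = None,
    **psth_kw,
) -> dict:
    """Peak post-stimulus probability vs input amplitude.

    threshold: smallest amplitude whose peak exceeds the baseline by more
    than ``threshold_excess``.  saturation: smallest amplitude beyond which
    every successive change of the peak is below ``saturation_frac`` of the
    overall peak range.
    """
    if basin is None:
        basin = rest_basin(params, I_mean)
    amplitudes = np.asarray(list(amplitudes), dtype=float)
    peaks = np.empty(len(amplitudes))
    base = np.empty(len(amplitudes))
    for i, Am in enumerate(amplitudes):
        r = psth(params, float(Am), sigma, sweeps=sweeps, seed=seed + i,
                 I_mean=I_mean, basin=basin, **psth_kw)
        post = r.t_centers_ms >= r.t_st_ms
        peaks[i] = r.p[post].max()
        base[i] = r.baseline
    baseline = float(np.median(base))
    above = np.where(peaks > baseline + threshold_excess)[0]
    thr = float(amplitudes[above[0]]) if len(above) else math.nan
    rng = peaks.max() - peaks.min()
    sat = math.nan
    if rng > 0:
        dchg = np.abs(np.diff(peaks))
        for i in range(len(amplitudes) - 1):
            if np.all(dchg[i:] < saturation_frac * rng):
                sat = float(amplitudes[i])
                break
    return {"Am": amplitudes, "peak": peaks, "baseline": baseline,
            "threshold": thr, "saturation": sat}


def vm_histogram(
    trace: VoltageTrace,
    state_labels: np.ndarray,
    bins: np.ndarray = None,
) -> dict:
    """Normalized membrane-potential histograms for spiking/silent states.

    ``state_labels`` is a per-sample boolean array (True = spiking state).
    Returns density histograms for each state and pooled.
    """
    if bins is None:
        bins = np.arange(-80.0, 0.0, 0.5)
    state_labels = np.asarray(state_labels, dtype=bool)
    if len(state_labels) != trace.n:
        raise ValueError("state_labels must align with the trace")
    out = {}
    for name, m in (("spiking", state_labels), ("silent", ~state_labels),
                    ("pooled", np.ones(trace.n, bool))):
        if m.any():
            h, edges = np.histogram(trace.V[m], bins=bins, density=True)
        else:
            h, edges = np.zeros(len(bins) - 1), bins
        out[name] = {"density": h, "edges": edges}
    return out
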