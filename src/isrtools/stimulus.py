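"""Stimulus waveform generation.

Current-clamp protocols used throughout the package:

* Ornstein-Uhlenbeck (OU) colored noise, the model of background synaptic
  input.  An OU process with mean ``mu``, stationary standard deviation
  ``sigma`` and correlation time ``tau`` obeys
  ``tau dx/dt = mu - x + sqrt(2 sigma^2 tau) N(0,1)``.
* The dual-OU injection used for dynamic I-V fitting (tau_fast = 3 ms and
  tau_slow = 10 ms, mimicking excitatory and inhibitory synaptic currents).
* Biexponential synaptic events (rise 1.5 ms, decay 10 ms), normalized so a
  single event peaks at its nominal amplitude.
* Step, ramp and pulse protocols for f-I curves, hysteresis and membrane
  time constant measurements.

All generators are deterministic given an integer seed.  OU series are
produced with the exact discrete-time update
``x <- mu + (x - mu) e^{-dt/tau} + sigma sqrt(1 - e^{-2 dt/tau}) z`` rather
than an Euler step, so the stationary statistics are exact at any dt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "OUSpec",
    "BiexpInputSpec",
    "Segment",
    "CurrentWaveform",
    "ou_series",
    "dual_ou_current",
    "biexp_kernel_norm",
    "biexp_current",
    "poisson_event_times",
    "build_protocol",
]


@dataclass(frozen=True)
class OUSpec:
    """Ornstein-Uhlenbeck process specification (mu, sigma in pA; tau in ms)."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass(frozen=True)
class BiexpInputSpec:
    """Biexponential synaptic input events.

    Each event at time ``t`` contributes
    ``Am/K(tau1,tau2) * (e^{-(s-t)/tau2} - e^{-(s-t)/tau1}) / (tau2-tau1)``,
    where K is chosen so the peak of one event equals ``Am``.
    """

    event_times_ms: Sequence[float]
    Am: float
    tau1: float = 1.5
    tau2: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.tau1:
            raise ValueError("tau1 must be > 0")
        if self.tau1 >= self.tau2:
            raise ValueError("need 0 < tau1 < tau2 (K undefined otherwise)")


@dataclass(frozen=True)
class Segment:
    """Annotation of a protocol segment: [start, start+n) samples."""

    label: str
    start: int
    n: int
    mean: float = 0.0
    sigma: float = 0.0


@dataclass
class CurrentWaveform:
    """Sampled injected-current waveform (pA) with protocol annotations."""

    dt: float
    samples: np.ndarray
    segments: List[Segment] = field(default_factory=list)
    #: optional per-sample noise amplitude (continuous-amplitude protocols)
    sigma_samples: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def duration_ms(self) -> float:
        return self.n * self.dt


def _ou_exact(n: int, dt: float, tau: float, sigma: float,
              rng: np.random.Generator) -> np.ndarray:
    """Zero-mean OU series via the exact AR(1) recursion (lfilter)."""
    if sigma == 0.0:
        return np.zeros(n)
    al = math.exp(-dt / tau)
    sd = sigma * math.sqrt(1.0 - al * al)
    z = rng.standard_normal(n)
    x0 = sigma * rng.standard_normal()  # stationary start
    y, _ = lfilter([sd], [1.0, -al], z, zi=np.array([al * x0]))
    return y


def ou_series(spec: OUSpec, dt: float, n: int, seed: int) -> CurrentWaveform:
    """Stationary OU noise series of ``n`` samples at step ``dt`` (ms)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = spec.mu + _ou_exact(n, dt, spec.tau, spec.sigma, rng)
    seg = [Segment("ou", 0, n, mean=spec.mu, sigma=spec.sigma)]
    return CurrentWaveform(dt=dt, samples=x, segments=seg)


def dual_ou_current(
    mean: float,
    sigma: float,
    dt: float,
    n: Optional[int] = None,
    seed: int = 0,
    *,
    tau_fast: float = 3.0,
    tau_slow: float = 10.0,
    fast_fraction: float = 0.5,
    lead_ms: float = 500.0,
    noise_ms: float = 20_000.0,
) -> CurrentWaveform:
    """Dynamic I-V injection: silent lead-in then dual-OU noise.

    The noise is the sum of two independent OU processes at ``tau_fast`` and
    ``tau_slow``; ``fast_fraction`` of the total variance ``sigma**2`` goes to
    the fast component (equal split by default).  Default shape: 500 ms at the
    holding mean followed by 20 s of noise.
    """
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(round((lead_ms + noise_ms) / dt))
    n_lead = min(int(round(lead_ms / dt)), n)
    n_noise = n - n_lead
    s_fast = sigma * math.sqrt(fast_fraction)
    s_slow = sigma * math.sqrt(1.0 - fast_fraction)
    x = np.full(n, mean)
    if n_noise > 0:
        x[n_lead:] += _ou_exact(n_noise, dt, tau_fast, s_fast, rng)
        x[n_lead:] += _ou_exact(n_noise, dt, tau_slow, s_slow, rng)
    segs = []
    if n_lead:
        segs.append(Segment("lead", 0, n_lead, mean=mean, sigma=0.0))
    if n_noise:
        segs.append(Segment("noise", n_lead, n_noise, mean=mean, sigma=sigma))
    return CurrentWaveform(dt=dt, samples=x, segments=segs)


def biexp_kernel_norm(tau1: float, tau2: float) -> float:
    """Peak value K(tau1, tau2) of the unit biexponential impulse response."""
    r = tau2 / tau1
    return (r ** (tau1 / (tau1 - tau2)) - r ** (tau2 / (tau1 - tau2))) / (
        tau2 - tau1
    )


def _biexp_kernel(dt: float, Am: float, tau1: float, tau2: float) -> np.ndarray:
    K = biexp_kernel_norm(tau1, tau2)
    t = np.arange(0.0, 10.0 * tau2, dt)
    return Am / K * (np.exp(-t / tau2) - np.exp(-t / tau1)) / (tau2 - tau1)


def biexp_current(spec: BiexpInputSpec, dt: float, n: int) -> CurrentWaveform:
    """Sum of biexponential synaptic events; each event peaks at ``Am``."""
    x = np.zeros(n)
    kern = _biexp_kernel(dt, spec.Am, spec.tau1, spec.tau2)
    for t in spec.event_times_ms:
        if not 0.0 <= t < n * dt:
            raise ValueError(f"event time {t} ms outside [0, {n * dt}) ms")
        i0 = int(t / dt)
        ln = min(len(kern), n - i0)
        x[i0:i0 + ln] += kern[:ln]
    segs = [Segment("biexp", 0, n, mean=0.0, sigma=0.0)]
    return CurrentWaveform(dt=dt, samples=x, segments=segs)


def poisson_event_times(rate_hz: float, T_ms: float, seed: int) -> np.ndarray:
    """Homogeneous Poisson event times in [0, T_ms), sorted (ms)."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * T_ms / 1000.0)
    return np.sort(rng.random(n) * T_ms)


def build_protocol(kind: str, *, dt: float = 0.1, seed: int = 0,
                   **kw) -> CurrentWaveform:
    """Build one of the named injection protocols.

    Kinds
    -----
    ``noise_steps``
        Alternating OU-noise epochs (default 1 s, tau = 2 ms) and rest epochs
        with stepped noise amplitude; keywords: ``mean``, ``sigmas``
        (default 0..500 pA in 50 pA steps), ``epoch_ms``, ``rest_ms``, ``tau``.
    ``continuous_noise``
        OU noise whose amplitude ramps linearly up and back down
        (default 0.5 nA/s) while the mean is held; keywords: ``mean``,
        ``sigma_max``, ``rate_pA_per_ms``, ``tau``.  The per-sample amplitude
        is stored in ``sigma_samples``.
    ``ramp``
        Symmetric current ramp (default 0.9 nA/s, 1 s up then 1 s down)
        repeated ``trials`` times from ``I_start``.
    ``current_steps``
        Series of constant steps (default 30 steps of 1 s, 50 pA increment)
        from ``I_start``.
    ``pulse``
        Brief square pulse (default 0.5 ms, 1 nA) on a holding current.
    """
    if kind == "noise_steps":
        mean = kw.get("mean", 0.0)
        sigmas = np.asarray(kw.get("sigmas", np.arange(0.0, 501.0, 50.0)),
                            dtype=float)
        epoch_ms = kw.get("epoch_ms", 1000.0)
        rest_ms = kw.get("rest_ms", 1000.0)
        tau = kw.get("tau", 2.0)
        ne = int(round(epoch_ms / dt))
        nr = int(round(rest_ms / dt))
        rng = np.random.default_rng(seed)
        parts, segs = [], []
        pos = 0
        for s in sigmas:
            rest = np.full(nr, mean)
            segs.append(Segment("rest", pos, nr, mean=mean, sigma=0.0))
            pos += nr
            noise = mean + _ou_exact(ne, dt, tau, float(s), rng)
            segs.append(Segment("noise", pos, ne, mean=mean, sigma=float(s)))
            pos += ne
            parts += [rest, noise]
        return CurrentWaveform(dt=dt, samples=np.concatenate(parts),
                               segments=segs)

    if kind == "continuous_noise":
        mean = kw.get("mean", 0.0)
        sigma_max = kw.get("sigma_max", 300.0)
        rate = kw.get("rate_pA_per_ms", 0.5)  # 0.5 nA/s
        tau = kw.get("tau", 2.0)
        cycles = kw.get("cycles", 20)
        n_half = int(round(sigma_max / rate / dt))
        sig = np.concatenate([
            rate * dt * np.arange(n_half),
            rate * dt * np.arange(n_half)[::-1],
        ])
        sig = np.tile(sig, cycles)
        rng = np.random.default_rng(seed)
        unit = _ou_exact(len(sig), dt, tau, 1.0, rng)
        wf = CurrentWaveform(
            dt=dt, samples=mean + unit * sig,
            segments=[Segment("continuous_noise", 0, len(sig),
                              mean=mean, sigma=sigma_max)],
        )
        wf.sigma_samples = sig
        return wf

    if kind == "ramp":
        I_start = kw.get("I_start", -650.0)
        rate = kw.get("rate_pA_per_ms", 0.9)  # 0.9 nA/s
        up_ms = kw.get("up_ms", 1000.0)
        trials = kw.get("trials", 10)
        n_half = int(round(up_ms / dt))
        up = I_start + rate * dt * np.arange(n_half)
        tri = np.concatenate([up, up[::-1]])
        segs = []
        for k in range(trials):
            segs.append(Segment("ramp_up", 2 * k * n_half, n_half,
                                mean=I_start))
            segs.append(Segment("ramp_down", (2 * k + 1) * n_half, n_half,
                                mean=I_start))
        return CurrentWaveform(dt=dt, samples=np.tile(tri, trials),
                               segments=segs)

    if kind == "current_steps":
        I_start = kw.get("I_start", -650.0)
        n_steps = kw.get("n_steps", 30)
        dI = kw.get("dI", 50.0)
        step_ms = kw.get("step_ms", 1000.0)
        ns = int(round(step_ms / dt))
        parts, segs = [], []
        for k in range(n_steps):
            I = I_start + k * dI
            parts.append(np.full(ns, I))
            segs.append(Segment("step", k * ns, ns, mean=I))
        return CurrentWaveform(dt=dt, samples=np.concatenate(parts),
                               segments=segs)

    if kind == "pulse":
        hold = kw.get("hold", 0.0)
        amp = kw.get("amp", 1000.0)  # 1 nA
        width_ms = kw.get("width_ms", 0.5)
        t_pulse = kw.get("t_pulse_ms", 500.0)
        total_ms = kw.get("total_ms", t_pulse + 300.0)
        n = int(round(total_ms / dt))
        x = np.full(n, hold)
        i0 = int(round(t_pulse / dt))
        i1 = i0 + max(1, int(round(width_ms / dt)))
        x[i0:i1] += amp
        segs = [Segment("hold", 0, i0, mean=hold),
                Segment("pulse", i0, i1 - i0, mean=hold + amp),
                Segment("hold", i1, n - i1, mean=hold)]
        return CurrentWaveform(dt=dt, samples=x, segments=segs)

    raise ValueError(f"unknown protocol kind {kind!r}")
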