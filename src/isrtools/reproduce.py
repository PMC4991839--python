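"""End-to-end drivers that recompute the published headline quantities.

Each function runs one complete protocol on the representative aEIF model
(or a synthetic population) from scratch and returns the measured numbers:
the ISR-optimal noise amplitude, PSTH baseline and decay constant, the
input-output threshold and saturation amplitudes, the mutual-information
peak, dynamic-IV parameter recovery, rheobase convergence, bistability
checks, CTW validation against analytic sources, and the hysteresis/ISR
parameter-dependence scans.  All randomness is controlled by the ``seed``
argument.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np
from scipy.stats import spearmanr

from .params import AEIFParams, classify_excitability, rheobase_up, \
    representative_cell
from .stimulus import BiexpInputSpec, OUSpec, biexp_current, dual_ou_current, \
    ou_series, poisson_event_times
from .integrator import SpikeTrain, integrate
from .phaseplane import BasinMask, bistable_range, rest_basin, rheobase_step
from .response import decay_time_constant, input_output_curve, \
    isr_curve_from_model, psth
from .infotheory import bin_spike_train, ctw_entropy_rate, mi_rate
from .dyniv import fit_full
from .synth import SyntheticCellSpec, adapted_holding_mean, \
    sample_population, synth_recording

__all__ = [
    "isr_optimum",
    "psth_baseline",
    "psth_decay",
    "mi_sweep",
    "io_thresholds",
    "population_recovery",
    "rheobase_convergence",
    "bistability_checks",
    "ctw_validation",
    "hysteresis_isr_correlation",
    "delta_i_scaling",
]


def _rep(params: Optional[AEIFParams]) -> AEIFParams:
    return params if params is not None else representative_cell()


def isr_optimum(params: Optional[AEIFParams] = None, seed: int = 1,
                I_mean: float = -150.0, reps: int = 20, T_s: float = 30.0,
                sigmas: Optional[Sequence[float]] = None) -> Dict:
    """Firing rate vs noise amplitude; the ISR-optimal sigma (argmin)."""
    p = _rep(params)
    if sigmas is None:
        sigmas = np.arange(0.0, 101.0, 10.0)
    curve = isr_curve_from_model(p, I_mean, sigmas, reps=reps,
                                 T_ms=T_s * 1000.0, seed=seed)
    return {"sigma_opt": curve.sigma_opt, "curve": curve,
            "n": int(reps * len(list(sigmas)))}


def psth_baseline(params: Optional[AEIFParams] = None, seed: int = 2,
                  sigma: float = 60.0, sweeps: int = 1000,
                  basin: Optional[BasinMask] = None) -> Dict:
    """Pre-stimulus spiking-state probability per 20 ms bin."""
    p = _rep(params)
    r = psth(p, 0.0, sigma, sweeps=sweeps, seed=seed, basin=basin)
    return {"baseline": r.baseline, "psth": r, "n": sweeps}


def psth_decay(params: Optional[AEIFParams] = None, seed: int = 3,
               sigma: float = 30.0, Am: float = 100.0, sweeps: int = 1000,
               basin: Optional[BasinMask] = None) -> Dict:
    """Decay constant of the stimulus-evoked spiking-state probability."""
    p = _rep(params)
    r = psth(p, Am, sigma, sweeps=sweeps, seed=seed, basin=basin)
    d = decay_time_constant(r)
    return {"tau_s": d["tau_s"], "psth": r, "fit": d, "n": sweeps}


def mi_sweep(params: Optional[AEIFParams] = None, seed: int = 4,
             sigmas: Sequence[float] = (10.0, 20.0, 30.0, 40.0, 60.0, 80.0),
             T_s: float = 300.0, repeats: int = 3, Am: float = 100.0,
             rate_hz: float = 1.0, I_mean: float = -150.0,
             depth: int = 40) -> Dict:
    """CTW mutual information rate between a Poisson input train and the
    model's output spikes, for each noise amplitude; reports the argmax."""
    p = _rep(params)
    basin = rest_basin(p, I_mean)
    fp = basin.fixed_point
    dt = 0.1
    T = T_s * 1000.0
    n = int(T / dt)
    out = {}
    for si, sig in enumerate(sigmas):
        vals = []
        for r in range(repeats):
            sub = (seed * 10_007 + si * 101 + r) % (2 ** 31 - 1)
            tev = poisson_event_times(rate_hz, T, seed=sub)
            syn = biexp_current(BiexpInputSpec(tuple(tev), Am), dt, n).samples
            wf = ou_series(OUSpec(I_mean, float(sig), 2.0), dt, n,
                           seed=sub + 1)
            wf.samples += syn
            _, train, _ = integrate(p, wf, init=(fp.V, fp.w), record=False)
            X = bin_spike_train(SpikeTrain(tev, T), 25.0, T)
            Y = bin_spike_train(train, 25.0, T)
            vals.append(mi_rate(X, Y, depth=depth).mi_bits_per_s)
        out[float(sig)] = float(np.mean(vals))
    best = max(out, key=out.get)
    return {"mi_bits_per_s": out, "sigma_peak": best,
            "n": int(len(list(sigmas)) * repeats)}


def io_thresholds(params: Optional[AEIFParams] = None, seed: int = 5,
                  sigma: float = 30.0, sweeps: int = 500,
                  amplitudes: Optional[Sequence[float]] = None,
                  basin: Optional[BasinMask] = None) -> Dict:
    """Input-output curve: response threshold and saturation amplitudes."""
    p = _rep(params)
    if amplitudes is None:
        amplitudes = np.arange(0.0, 151.0, 12.5)
    r = input_output_curve(p, sigma, amplitudes, sweeps=sweeps, seed=seed,
                           basin=basin)
    r["n"] = int(sweeps * len(list(amplitudes)))
    return r


def population_recovery(n_cells: int = 20, seed: int = 6,
                        noise_s: float = 20.0) -> Dict:
    """Dynamic-IV pipeline recovery on a synthetic population.

    Each cell gets a dual-OU recording (sigma = 153 pA, holding mean adapted
    per cell as in the experiments) and is fitted with ``fit_full``; per-cell
    relative errors, their medians, and excitability classifications are
    returned.
    """
    cells = sample_population(n_cells, seed=seed)
    keys = ("C", "EL", "VT", "DeltaT", "a", "b", "tau_w")
    errors = {k: [] for k in keys}
    classes = []
    for i, cell in enumerate(cells):
        mean = adapted_holding_mean(cell.params, seed=seed * 101 + i)
        proto = dual_ou_current(mean=mean, sigma=153.0, dt=0.01,
                                seed=seed * 313 + i,
                                noise_ms=noise_s * 1000.0)
        rec = synth_recording(cell, proto)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted, _ = fit_full(rec, None)
        for k in keys:
            tv, fv = getattr(cell.params, k), getattr(fitted, k)
            errors[k].append(abs(fv - tv) / abs(tv))
        classes.append((cell.excitability, classify_excitability(fitted)))
    medians = {k: float(np.median(v)) for k, v in errors.items()}
    return {"median_rel_error": medians, "errors": errors,
            "classes": classes, "n": n_cells}


def rheobase_convergence(params: Optional[AEIFParams] = None) -> Dict:
    """Closed-form rheobase vs the step-protocol bisection estimate."""
    p = _rep(params)
    closed = rheobase_up(p)
    step = rheobase_step(p)
    return {"closed_form": closed, "step_protocol": step,
            "abs_diff": abs(closed - step)}


def bistability_checks(params: Optional[AEIFParams] = None,
                       seed: int = 7) -> Dict:
    """Bistable interval and presence/absence of noise-induced inhibition.

    The interval [I_down, I_up] comes from the quasi-static step protocols;
    ISR presence at a holding mean is judged by whether intermediate noise
    reduces the firing rate well below the noise-free rate.
    """
    p = _rep(params)
    lo, hi = bistable_range(p)
    suppression = {}
    for I_mean in (-100.0, -150.0, -200.0):
        c = isr_curve_from_model(p, I_mean, np.arange(0.0, 61.0, 10.0),
                                 reps=5, T_ms=10_000.0, seed=seed)
        f0 = max(c.rate[0], 1e-9)
        suppression[I_mean] = float(1.0 - c.rate.min() / f0) \
            if c.rate[0] > 1.0 else 0.0
    return {"I_down": lo, "I_up": hi, "suppression": suppression}


def ctw_validation(n: int = 100_000, seed: int = 8) -> Dict:
    """CTW entropy-rate error against analytic Bernoulli/Markov sources."""
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < 0.5).astype(int)
    err_b = abs(ctw_entropy_rate(x, 40, 2) - 1.0)
    P = np.array([[0.9, 0.1], [0.3, 0.7]])
    s = np.empty(n, int)
    s[0] = 0
    u = rng.random(n)
    for i in range(1, n):
        s[i] = 0 if u[i] < P[s[i - 1], 0] else 1
    pi = np.array([0.75, 0.25])
    H = float(-(pi[:, None] * P * np.log2(P)).sum())
    err_m = abs(ctw_entropy_rate(s, 40, 2) - H)
    return {"bernoulli_error": float(err_b), "markov_error": float(err_m),
            "n": n}


_FAMILY = ((25.0, 12.0), (30.0, 16.0), (38.0, 21.0), (45.0, 26.0),
           (55.0, 32.0), (20.0, 28.0), (50.0, 14.0))


def hysteresis_isr_correlation(seed: int = 9, reps: int = 4,
                               T_s: float = 10.0) -> Dict:
    """Rank correlation between the bistable range Delta I and the
    ISR-optimal noise amplitude across a family of cells varying adaptation
    strength and time constant.  Each cell is probed at the midpoint of its
    own bistable interval (holding mean adapted per cell)."""
    base = representative_cell()
    dIs, sopts = [], []
    for k, (a, tw) in enumerate(_FAMILY):
        q = base.with_(a=a, tau_w=tw)
        lo, hi = bistable_range(q)
        c = isr_curve_from_model(q, 0.5 * (lo + hi),
                                 np.arange(0.0, 151.0, 10.0), reps=reps,
                                 T_ms=T_s * 1000.0, seed=seed * 37 + k)
        dIs.append(hi - lo)
        sopts.append(c.sigma_opt)
    rho = float(spearmanr(dIs, sopts).statistic)
    return {"delta_I": dIs, "sigma_opt": sopts, "spearman": rho,
            "n": len(_FAMILY)}


def delta_i_scaling(A_grid=(2.0, 3.0, 4.0, 5.0, 6.0),
                    T_grid=(0.3, 0.6, 1.2, 2.4)) -> Dict:
    """Dependence of the bistable range on the rescaled parameters.

    Delta I grows approximately linearly with A = a/gL and sublinearly
    (concave, per doubling) with T = tau_w/tau_m.
    """
    base = representative_cell()
    dI_A = []
    for A in A_grid:
        lo, hi = bistable_range(base.with_(a=A * base.gL))
        dI_A.append(hi - lo)
    dI_T = []
    for T in T_grid:
        lo, hi = bistable_range(base.with_(tau_w=T * base.tau_m))
        dI_T.append(hi - lo)
    A = np.asarray(A_grid)
    y = np.asarray(dI_A)
    coef = np.polyfit(A, y, 1)
    r2 = 1.0 - np.sum((y - np.polyval(coef, A)) ** 2) / np.sum(
        (y - y.mean()) ** 2)
    increments_T = np.diff(dI_T)  # per doubling of T
    return {"A": list(A_grid), "dI_A": dI_A, "linear_r2_A": float(r2),
            "T": list(T_grid), "dI_T": dI_T,
            "doubling_increments_T": increments_T.tolist()}
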