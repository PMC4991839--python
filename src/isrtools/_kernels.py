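"""Numba-compiled forward-Euler integration kernels.

All kernels take the aEIF parameters as scalars (C pF, gL nS, EL mV, VT mV,
DT mV, a nS, b pA, tw ms, Vr mV, Vsp mV) and an injected-current array in pA
sampled at ``dt`` ms.  Spikes are recorded at the sample index where V first
exceeds Vsp; the reset (V <- Vr, w <- w + b) applies within the same step.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def aeif_record(C, gL, EL, VT, DT, a, b, tw, Vr, Vsp, I, dt, V0, w0):
    """Integrate recording V(t), w(t); returns (V, w, spike_indices)."""
    n = I.shape[0]
    V = V0
    w = w0
    Vt = np.empty(n)
    wt = np.empty(n)
    spikes = np.empty(n, np.int64)
    ns = 0
    for i in range(n):
        dV = (-gL * (V - EL) + gL * DT * np.exp((V - VT) / DT) - w + I[i]) / C
        dw = (a * (V - EL) - w) / tw
        V += dt * dV
        w += dt * dw
        if V > Vsp:
            spikes[ns] = i
            ns += 1
            V = Vr
            w = w + b
        Vt[i] = V
        wt[i] = w
    return Vt, wt, spikes[:ns]


@njit(cache=True)
def aeif_spikes(C, gL, EL, VT, DT, a, b, tw, Vr, Vsp, I, dt, V0, w0):
    """Integrate recording spikes only; returns (spike_indices, V_end, w_end)."""
    n = I.shape[0]
    V = V0
    w = w0
    spikes = np.empty(n, np.int64)
    ns = 0
    for i in range(n):
        dV = (-gL * (V - EL) + gL * DT * np.exp((V - VT) / DT) - w + I[i]) / C
        dw = (a * (V - EL) - w) / tw
        V += dt * dV
        w += dt * dw
        if V > Vsp:
            spikes[ns] = i
            ns += 1
            V = Vr
            w = w + b
    return spikes[:ns], V, w


@njit(cache=True)
def aeif_occupancy(C, gL, EL, VT, DT, a, b, tw, Vr, Vsp, I, dt, V0, w0,
                   mask, vmin, dv, wmin, dwid, binsteps):
    """Integrate and accumulate, per time bin of ``binsteps`` samples, the
    fraction of samples spent *outside* the rest-state basin ``mask``, and
    whether the bin contains at least one spike.

    Grid convention: cell (iv, iw) covers V in [vmin+iv*dv, ...), w likewise.
    Samples falling outside the grid are counted as outside the basin.
    Returns (outside_fraction per bin, spike_flag per bin, spike_indices).
    """
    n = I.shape[0]
    nv = mask.shape[0]
    nw = mask.shape[1]
    nb = n // binsteps
    out = np.zeros(nb)
    spk_bin = np.zeros(nb, np.bool_)
    spikes = np.empty(n, np.int64)
    ns = 0
    V = V0
    w = w0
    for i in range(n):
        dV = (-gL * (V - EL) + gL * DT * np.exp((V - VT) / DT) - w + I[i]) / C
        dw = (a * (V - EL) - w) / tw
        V += dt * dV
        w += dt * dw
        bi = i // binsteps
        if V > Vsp:
            spikes[ns] = i
            ns += 1
            V = Vr
            w = w + b
            if bi < nb:
                spk_bin[bi] = True
        if bi < nb:
            iv = int((V - vmin) / dv)
            iw = int((w - wmin) / dwid)
            inside = False
            if 0 <= iv < nv and 0 <= iw < nw:
                inside = mask[iv, iw]
            if not inside:
                out[bi] += 1.0
    return out / binsteps, spk_bin, spikes[:ns]


@njit(cache=True)
def basin_grid(C, gL, EL, VT, DT, a, b, tw, Vr, Vsp, I, dt,
               Vg, wg, Vstar, wstar, horizon_steps, vtol, wtol):
    """Noise-free basin-of-attraction membership on a (V, w) grid.

    A grid point belongs to the rest basin iff its noise-free trajectory
    produces no spike within the horizon and ends within (vtol, wtol) of the
    stable fixed point (Vstar, wstar).
    """
    nv = Vg.shape[0]
    nw = wg.shape[0]
    M = np.zeros((nv, nw), np.bool_)
    for i in range(nv):
        for j in range(nw):
            V = Vg[i]
            w = wg[j]
            ok = True
            for s in range(horizon_steps):
                dV = (-gL * (V - EL) + gL * DT * np.exp((V - VT) / DT)
                      - w + I) / C
                dw = (a * (V - EL) - w) / tw
                V += dt * dV
                w += dt * dw
                if V > Vsp:
                    ok = False
                    break
                if (abs(V - Vstar) < 0.25 * vtol and
                        abs(w - wstar) < 0.25 * wtol and s > 10):
                    break
            if ok and abs(V - Vstar) < vtol and abs(w - wstar) < wtol:
                M[i, j] = True
    return M


@njit(cache=True)
def twocomp_record(C, gL, EL, VT, DT, a, b, tw, Vr, Vsp, gc, Cd, gLd,
                   I, dt, V0, w0, Vd0):
    """Two-compartment (soma + passive dendrite) forward Euler."""
    n = I.shape[0]
    V = V0
    w = w0
    Vd = Vd0
    Vt = np.empty(n)
    wt = np.empty(n)
    Vdt = np.empty(n)
    spikes = np.empty(n, np.int64)
    ns = 0
    for i in range(n):
        dV = (-gL * (V - EL) + gL * DT * np.exp((V - VT) / DT) - w
              + gc * (Vd - V) + I[i]) / C
        dw = (a * (V - EL) - w) / tw
        dVd = (-gLd * (Vd - EL) + gc * (V - Vd)) / Cd
        V += dt * dV
        w += dt * dw
        Vd += dt * dVd
        if V > Vsp:
            spikes[ns] = i
            ns += 1
            V = Vr
            w = w + b
        Vt[i] = V
        wt[i] = w
        Vdt[i] = Vd
    return Vt, wt, Vdt, spikes[:ns]


@njit(cache=True)
def reconstruct_w(V, dt, spk_idx, EL, a, tw, b, w0):
    """Reconstruct the adaptation current from a measured voltage trace.

    Integrates tau_w dw/dt = a (V - EL) - w along the recorded V(t), adding b
    at each detected spike sample.
    """
    n = V.shape[0]
    w = np.empty(n)
    x = w0
    si = 0
    m = spk_idx.shape[0]
    for i in range(n):
        x += dt * (a * (V[i] - EL) - x) / tw
        if si < m and spk_idx[si] == i:
            x += b
            si += 1
        w[i] = x
    return w
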