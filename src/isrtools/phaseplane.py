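"""Phase-plane and bifurcation analysis of the aEIF model.

In the bistable (type II) regime the subthreshold phase plane contains a
stable focus (the rest state) whose basin of attraction is a drop-shaped set;
everything outside the basin leads to a spike and, through the reset rule, to
repetitive firing.  This module locates fixed points and classifies them by
the Jacobian, finds the Andronov-Hopf current by bisection on the eigenvalue
real part, computes the rest basin on a (V, w) grid by noise-free forward
integration, measures the probability of spiking as the fraction of time a
noisy trajectory spends outside the basin (P_sp = 1 - P_r), and determines
the bistable current interval [I_down, I_up] with quasi-static step
protocols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from .params import AEIFParams
from .stimulus import OUSpec, ou_series
from .integrator import _ptuple, limit_cycle_state

__all__ = [
    "FixedPoint",
    "BasinMask",
    "HopfResult",
    "SpikingProbability",
    "find_fixed_points",
    "hopf_scan",
    "rest_basin",
    "spiking_probability",
    "rheobase_step",
    "spiking_offset_step",
    "bistable_range",
]


@dataclass(frozen=True)
class FixedPoint:
    """Fixed point of the subthreshold flow with its linear classification."""

    V: float
    w: float
    eigenvalues: Tuple[complex, complex]
    kind: str  # stable_focus | stable_node | unstable_focus | unstable_node | saddle

    @property
    def stable(self) -> bool:
        return self.kind.startswith("stable")


@dataclass
class BasinMask:
    """Boolean rest-basin membership on a (V, w) grid at fixed input I."""

    Vg: np.ndarray
    wg: np.ndarray
    mask: np.ndarray
    I: float
    fixed_point: FixedPoint

    @property
    def dv(self) -> float:
        return float(self.Vg[1] - self.Vg[0])

    @property
    def dw(self) -> float:
        return float(self.wg[1] - self.wg[0])

    def contains(self, V: float, w: float) -> bool:
        iv = int((V - self.Vg[0]) / self.dv)
        iw = int((w - self.wg[0]) / self.dw)
        if 0 <= iv < len(self.Vg) and 0 <= iw < len(self.wg):
            return bool(self.mask[iv, iw])
        return False


def _nullcline_residual(V: float, params: AEIFParams, I: float) -> float:
    # dV/dt = 0 with w on the w-nullcline (w = a (V - EL))
    return (
        -(params.gL + params.a) * (V - params.EL)
        + params.gL * params.DeltaT
        * math.exp((V - params.VT) / params.DeltaT)
        + I
    )


def _jacobian(params: AEIFParams, V: float) -> np.ndarray:
    dfdV = (-params.gL + params.gL
            * math.exp((V - params.VT) / params.DeltaT)) / params.C
    return np.array([
        [dfdV, -1.0 / params.C],
        [params.a / params.tau_w, -1.0 / params.tau_w],
    ])


def _classify(eigs: np.ndarray) -> str:
    if np.iscomplexobj(eigs) and abs(eigs[0].imag) > 1e-12:
        return "stable_focus" if eigs[0].real < 0 else "unstable_focus"
    ev = np.real(eigs)
    if ev[0] * ev[1] < 0:
        return "saddle"
    return "stable_node" if max(ev) < 0 else "unstable_node"


def find_fixed_points(
    params: AEIFParams, I: float,
    V_range: Tuple[float, float] = (-90.0, 0.0),
    scan_mV: float = 0.01,
) -> List[FixedPoint]:
    """All fixed points in ``V_range``, classified via the Jacobian.

    Roots of the reduced 1-D equation (V-nullcline intersected with the
    w-nullcline) are bracketed by a dense sign scan and polished by Brent's
    method.  An empty list is a valid result above the fold.
    """
    Vs = np.arange(V_range[0], V_range[1] + scan_mV, scan_mV)
    vals = (
        -(params.gL + params.a) * (Vs - params.EL)
        + params.gL * params.DeltaT
        * np.exp((Vs - params.VT) / params.DeltaT)
        + I
    )
    out: List[FixedPoint] = []
    sign = np.sign(vals)
    idx = np.where(np.diff(sign) != 0)[0]
    for i in idx:
        V = brentq(_nullcline_residual, Vs[i], Vs[i + 1], args=(params, I),
                   xtol=1e-12)
        w = params.a * (V - params.EL)
        eigs = np.linalg.eigvals(_jacobian(params, V))
        out.append(FixedPoint(V=V, w=w, eigenvalues=(eigs[0], eigs[1]),
                              kind=_classify(eigs)))
    return out


@dataclass(frozen=True)
class HopfResult:
    """Stability-change scan result."""

    found: bool
    I: float = math.nan
    omega: float = math.nan  # imaginary part at the crossing (rad/ms)

    @property
    def is_hopf(self) -> bool:
        return self.found and abs(self.omega) > 1e-9


def _low_fp_max_real(params: AEIFParams, I: float) -> Optional[float]:
    fps = find_fixed_points(params, I)
    if not fps:
        return None
    fp = min(fps, key=lambda f: f.V)
    return max(e.real for e in fp.eigenvalues)


def hopf_scan(params: AEIFParams, I_range: Tuple[float, float] = (-400.0, 0.0),
              dI: float = 5.0) -> HopfResult:
    """Locate the current at which the low-V fixed point loses stability.

    Bisection on the maximum real part of the Jacobian eigenvalues.  A
    nonzero imaginary part at the crossing marks an Andronov-Hopf bifurcation
    (type II); a zero imaginary part marks a saddle-node (type I).
    """
    lo, hi = I_range
    grid = np.arange(lo, hi + dI, dI)
    prev_I = None
    prev_s = None
    bracket = None
    for I in grid:
        s = _low_fp_max_real(params, float(I))
        if s is None:
            # fixed points vanished; treat disappearance as loss of stability
            if prev_s is not None and prev_s < 0:
                bracket = (prev_I, float(I))
            break
        if prev_s is not None and prev_s < 0 <= s:
            bracket = (prev_I, float(I))
            break
        prev_I, prev_s = float(I), s
    if bracket is None:
        return HopfResult(found=False)
    lo, hi = bracket
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        s = _low_fp_max_real(params, mid)
        if s is None or s >= 0:
            hi = mid
        else:
            lo = mid
    fps = find_fixed_points(params, lo)
    fp = min(fps, key=lambda f: f.V)
    omega = abs(fp.eigenvalues[0].imag)
    return HopfResult(found=True, I=0.5 * (lo + hi), omega=omega)


def rest_basin(
    params: AEIFParams,
    I: float,
    V_bounds: Tuple[float, float] = (-90.0, 0.0),
    w_bounds: Tuple[float, float] = (-400.0, 1200.0),
    dv: float = 0.25,
    dw: float = 5.0,
    horizon_ms: float = 500.0,
    dt: float = 0.1,
    vtol: float = 1.0,
    wtol: float = 20.0,
) -> BasinMask:
    """Rest-state basin of attraction on a (V, w) grid.

    Each cell is integrated noise-free for ``horizon_ms``; membership requires
    no spike and an endpoint within (vtol, wtol) of the stable fixed point.
    """
    fps = [f for f in find_fixed_points(params, I) if f.stable]
    if not fps:
        raise ValueError(f"no stable fixed point at I={I} pA")
    fp = fps[0]
    Vg = np.arange(V_bounds[0], V_bounds[1], dv)
    wg = np.arange(w_bounds[0], w_bounds[1], dw)
    M = _kernels.basin_grid(
        *_ptuple(params), float(I), dt, Vg, wg, fp.V, fp.w,
        int(horizon_ms / dt), vtol, wtol)
    return BasinMask(Vg=Vg, wg=wg, mask=M, I=float(I), fixed_point=fp)


@dataclass
class SpikingProbability:
    """P_sp = 1 - P_r averaged over repetitions, with per-rep values."""

    P_sp: float
    sd: float
    per_rep: np.ndarray
    sigma: float
    I_mean: float


def spiking_probability(
    params: AEIFParams,
    I_mean: float,
    sigma: float,
    reps: int = 20,
    T_ms: float = 30_000.0,
    seed: int = 0,
    *,
    tau_noise: float = 2.0,
    dt: float = 0.1,
    init: str = "limit_cycle",
    basin: Optional[BasinMask] = None,
) -> SpikingProbability:
    """Probability of spiking under OU noise at (I_mean, sigma).

    P_r is the fraction of integration time the trajectory's (V, w) lies
    inside the rest basin (instantaneous nearest-cell membership); P_sp is
    1 - P_r, averaged over ``reps`` independent repetitions of ``T_ms``.
    If no stable fixed point exists, P_sp = 1 by convention.
    """
    try:
        if basin is None:
            basin = rest_basin(params, I_mean)
    except ValueError:
        per = np.ones(reps)
        return SpikingProbability(1.0, 0.0, per, sigma, I_mean)
    if init == "limit_cycle":
        V0, w0 = limit_cycle_state_or_fallback(params, I_mean)
    elif init == "rest":
        V0, w0 = basin.fixed_point.V, basin.fixed_point.w
    else:
        raise ValueError("init must be 'limit_cycle' or 'rest'")
    n = int(T_ms / dt)
    per = np.empty(reps)
    for r in range(reps):
        wf = ou_series(OUSpec(mu=I_mean, sigma=sigma, tau=tau_noise), dt, n,
                       seed=seed * 100_003 + r)
        out, _, _ = _kernels.aeif_occupancy(
            *_ptuple(params), wf.samples, dt, V0, w0,
            basin.mask, basin.Vg[0], basin.dv, basin.wg[0], basin.dw, n)
        per[r] = out[0]
    return SpikingProbability(float(per.mean()), float(per.std()), per,
                              sigma, I_mean)


def limit_cycle_state_or_fallback(params: AEIFParams, I: float):
    """Limit-cycle state at I, or at a clearly suprathreshold current if the
    cycle does not exist at I (the trajectory then starts 'spiking')."""
    try:
        return limit_cycle_state(params, I)
    except ValueError:
        return limit_cycle_state(params, I + 500.0)


def rheobase_step(
    params: AEIFParams,
    bracket: Tuple[float, float] = (-400.0, 100.0),
    horizon_ms: float = 5_000.0,
    dt: float = 0.1,
    tol: float = 0.25,
) -> float:
    """Quasi-static rheobase: minimal constant current that elicits a spike
    when the model starts from the rest state (bisection on step protocols).

    The model is initialized a hair (0.01 mV) off the low-V fixed point; if
    no fixed point exists the current counts as spiking.
    """
    def spikes(I: float) -> bool:
        fps = find_fixed_points(params, I)
        if not fps:
            return True
        fp = min(fps, key=lambda f: f.V)
        n = int(horizon_ms / dt)
        spk, _, _ = _kernels.aeif_spikes(
            *_ptuple(params), np.full(n, I), dt, fp.V + 0.01, fp.w)
        return len(spk) > 0

    lo, hi = bracket
    if spikes(lo):
        raise ValueError("bracket low end already spikes")
    if not spikes(hi):
        raise ValueError("bracket high end does not spike")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spikes(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def spiking_offset_step(
    params: AEIFParams,
    bracket: Tuple[float, float] = (-400.0, 0.0),
    horizon_ms: float = 5_000.0,
    dt: float = 0.1,
    tol: float = 0.5,
) -> float:
    """Maximal constant current at which spiking stops, starting from the
    periodic spiking state (bisection; I_down of the bistable range)."""
    def sustained(I: float) -> bool:
        n = int(horizon_ms / dt)
        spk, _, _ = _kernels.aeif_spikes(
            *_ptuple(params), np.full(n, I), dt, -40.0, 0.0)
        return len(spk) > 0 and spk[-1] > 0.7 * n

    lo, hi = bracket
    if sustained(lo):
        raise ValueError("bracket low end sustains spiking")
    if not sustained(hi):
        raise ValueError("bracket high end does not sustain spiking")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if sustained(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def bistable_range(params: AEIFParams, **kw) -> Tuple[float, float]:
    """Bistable current interval [I_down, I_up] from step protocols.

    I_up is the minimal constant current eliciting a spike from rest (the
    rheobase; equals the closed form for type II parameters) and I_down the
    maximal current at which spiking stops from the periodic state.
    """
    I_up = rheobase_step(params, **kw.get("up_kw", {}))
    I_down = spiking_offset_step(params, **kw.get("down_kw", {}))
    return I_down, I_up
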