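"""Forward-Euler integration of the aEIF model and trace containers.

The standard integration step is dt = 0.1 ms; synthetic recordings are
integrated at finer steps (0.01-0.02 ms) and resampled.  Spike times follow
the left-edge convention: the time of the sample at which V first exceeds
Vspike.  The reset applies within the same integration step (no refractory
hold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from . import _kernels
from .params import AEIFParams, TwoCompartmentParams
from .stimulus import CurrentWaveform

__all__ = ["VoltageTrace", "SpikeTrain", "integrate", "rest_state",
            "limit_cycle_state"]


@dataclass
class VoltageTrace:
    """Aligned voltage recording and injected current (mV / pA at dt ms)."""

    dt: float
    V: np.ndarray
    I_in: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=np.float64)
        self.I_in = np.asarray(self.I_in, dtype=np.float64)
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if len(self.V) != len(self.I_in):
            raise ValueError("V and I_in must be sampled alike")

    @property
    def n(self) -> int:
        return len(self.V)

    @property
    def duration_ms(self) -> float:
        return self.n * self.dt

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(self.n) * self.dt


@dataclass
class SpikeTrain:
    """Sorted spike times in ms within [0, duration_ms)."""

    times_ms: np.ndarray
    duration_ms: float

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=np.float64)
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if len(self.times_ms) and not (
            0 <= self.times_ms[0] and self.times_ms[-1] < self.duration_ms
        ):
            raise ValueError("spike times must lie within the trace duration")

    def __len__(self) -> int:
        return len(self.times_ms)

    @property
    def rate_hz(self) -> float:
        return len(self.times_ms) / (self.duration_ms / 1000.0)


def _ptuple(p: AEIFParams):
    return (p.C, p.gL, p.EL, p.VT, p.DeltaT, p.a, p.b, p.tau_w, p.Vr,
            p.Vspike)


def _upsample(current: CurrentWaveform, dt: float) -> np.ndarray:
    """Current samples at integration step dt (must equal or subdivide)."""
    ratio = current.dt / dt
    k = int(round(ratio))
    if not np.isclose(ratio, k) or k < 1:
        raise ValueError(
            f"integration dt={dt} must equal or subdivide waveform dt="
            f"{current.dt}"
        )
    if k == 1:
        return current.samples
    return np.repeat(current.samples, k)


def integrate(
    params,
    current: CurrentWaveform,
    init: Optional[Tuple[float, ...]] = None,
    dt: float = 0.1,
    record: bool = True,
):
    """Integrate the model driven by ``current``.

    Parameters
    ----------
    params : AEIFParams or TwoCompartmentParams
    current : CurrentWaveform
        Injected current; its dt must be a multiple of the integration dt.
    init : tuple, optional
        Initial state (V, w) (or (V, w, Vd)); defaults to (EL, 0).
    dt : float
        Integration step in ms (default 0.1).
    record : bool
        If False, only spikes and the final state are kept (less memory).

    Returns
    -------
    (VoltageTrace or None, SpikeTrain, w_trace or (V_end, w_end))
    """
    I = _upsample(current, dt)
    two = isinstance(params, TwoCompartmentParams)
    soma = params.soma if two else params
    if init is None:
        init = (soma.EL, 0.0, soma.EL) if two else (soma.EL, 0.0)
    if two:
        V0, w0, Vd0 = init
        Vt, wt, Vdt, spk = _kernels.twocomp_record(
            *_ptuple(soma), params.gc, params.Cd, params.gLd,
            I, dt, V0, w0, Vd0)
        if not np.isfinite(Vt[-1]):
            raise FloatingPointError("numerical overflow during integration")
        train = SpikeTrain(spk * dt, len(I) * dt)
        trace = VoltageTrace(dt, Vt, I, meta={"source": "simulated",
                                              "Vd": Vdt})
        return trace, train, wt
    V0, w0 = init
    if record:
        Vt, wt, spk = _kernels.aeif_record(*_ptuple(soma), I, dt, V0, w0)
        if not np.isfinite(Vt[-1]):
            raise FloatingPointError("numerical overflow during integration")
        trace = VoltageTrace(dt, Vt, I, meta={"source": "simulated"})
        return trace, SpikeTrain(spk * dt, len(I) * dt), wt
    spk, Ve, we = _kernels.aeif_spikes(*_ptuple(soma), I, dt, V0, w0)
    return None, SpikeTrain(spk * dt, len(I) * dt), (Ve, we)


def rest_state(params: AEIFParams, I: float, dt: float = 0.1,
               settle_ms: float = 20_000.0) -> Tuple[float, float]:
    """Relax the noise-free model from a hyperpolarized start to the rest
    fixed point at constant input I; raises if it keeps spiking."""
    n = int(settle_ms / dt)
    spk, Ve, we = _kernels.aeif_spikes(
        *_ptuple(params), np.full(n, float(I)), dt, params.EL - 5.0,
        params.a * (params.EL - 5.0 - params.EL))
    if len(spk) and spk[-1] > 0.8 * n:
        raise ValueError(f"no rest state reached at I={I} pA")
    return Ve, we


def limit_cycle_state(params: AEIFParams, I: float, dt: float = 0.1,
                      settle_ms: float = 5_000.0) -> Tuple[float, float]:
    """A point on the noise-free spiking limit cycle at constant input I.

    Returns the state just after the last reset; raises if spiking is not
    sustained at this input.
    """
    n = int(settle_ms / dt)
    Vt, wt, spk = _kernels.aeif_record(
        *_ptuple(params), np.full(n, float(I)), dt, -40.0, 0.0)
    if len(spk) == 0 or spk[-1] < 0.7 * n:
        raise ValueError(f"no sustained spiking at I={I} pA")
    k = spk[-1]  # stored state at the spike sample is just after the reset
    return float(Vt[k]), float(wt[k])
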