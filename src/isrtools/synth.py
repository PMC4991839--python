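"""Synthetic recordings emulating Purkinje-cell patch-clamp data.

No recordings are deposited for this preparation, so every pipeline stage is
exercised on traces generated from ground-truth aEIF cells: the model is
integrated at a fine step, resampled to the 50 kHz acquisition rate, and
white measurement noise is added to the voltage (the injected current is
stored losslessly).  A population of cells is drawn from the published
parameter statistics (truncated normals, independent coordinates, redrawn
until type II, matching the recorded population).  Fitting code never sees the ground truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .params import AEIFParams, classify_excitability, representative_cell
from .stimulus import (CurrentWaveform, build_protocol, dual_ou_current)
from .integrator import VoltageTrace, integrate

__all__ = ["SyntheticCellSpec", "sample_population", "synth_recording",
           "fixture_suite", "POPULATION_STATS"]

#: published population mean +- SD (n = 7 fitted cells)
POPULATION_STATS = {
    "C": (195.4, 53.3),        # pF
    "tau_m": (4.4, 1.2),       # ms; gL = C / tau_m
    "EL": (-51.9, 1.9),        # mV
    "VT": (-54.1, 2.3),        # mV
    "DeltaT": (1.0, 0.2),      # mV
    "a": (36.1, 6.3),          # nS
    "b": (408.0, 128.0),       # pA
    "tau_w": (14.8, 6.3),      # ms
}

_LOWER = {"C": 60.0, "tau_m": 1.5, "EL": -60.0, "VT": -62.0, "DeltaT": 0.3,
          "a": 5.0, "b": 50.0, "tau_w": 4.0}
_UPPER = {"C": 400.0, "tau_m": 10.0, "EL": -44.0, "VT": -46.0, "DeltaT": 2.0,
          "a": 80.0, "b": 900.0, "tau_w": 40.0}


@dataclass
class SyntheticCellSpec:
    """Ground truth plus acquisition settings for one synthetic cell."""

    params: AEIFParams
    noise_sd_mV: float = 0.2
    fs_khz: float = 50.0
    seed: int = 0
    excitability: str = ""

    def __post_init__(self) -> None:
        if not self.excitability:
            self.excitability = classify_excitability(self.params)


def _draw(rng: np.random.Generator, key: str) -> float:
    mu, sd = POPULATION_STATS[key]
    for _ in range(1000):
        x = rng.normal(mu, sd)
        if _LOWER[key] <= x <= _UPPER[key]:
            return float(x)
    return mu


def sample_population(n: int, seed: int = 0, *,
                      require_type_ii: bool = True,
                      noise_sd_mV: float = 0.2) -> List[SyntheticCellSpec]:
    """Draw ``n`` cells from the published population statistics.

    Coordinates are sampled independently from truncated normals; draws are
    repeated until the cell is type II (all recorded cells lie in the
    type II region).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cells = []
    while len(cells) < n:
        vals = {k: _draw(rng, k) for k in POPULATION_STATS}
        p = AEIFParams(
            C=vals["C"], gL=vals["C"] / vals["tau_m"], EL=vals["EL"],
            VT=vals["VT"], DeltaT=vals["DeltaT"], a=vals["a"], b=vals["b"],
            tau_w=vals["tau_w"], Vr=-60.0, Vspike=0.0)
        if require_type_ii and classify_excitability(p) != "type_II":
            continue
        cells.append(SyntheticCellSpec(
            params=p, noise_sd_mV=noise_sd_mV,
            seed=int(rng.integers(0, 2 ** 31 - 1))))
    return cells


def adapted_holding_mean(params: AEIFParams, sigma: float = 153.0,
                         target_hz: float = 25.0, seed: int = 0) -> float:
    """Holding mean for the dynamic-IV protocol, adapted per cell.

    As in the experiments, the holding current is chosen per cell so the
    noise-driven firing rate is moderate (enough spikes for the adaptation
    fit, enough subthreshold data outside the post-spike exclusion windows).
    Candidate means are probed with short dual-OU injections; the one whose
    rate is closest to ``target_hz`` wins.
    """
    best, best_d = 0.0, np.inf
    for mean in np.arange(400.0, -1401.0, -100.0):
        proto = dual_ou_current(mean=mean, sigma=sigma, dt=0.05, seed=seed,
                                lead_ms=200.0, noise_ms=3000.0)
        _, train, _ = integrate(params, proto, dt=0.05, record=False)
        d = abs(train.rate_hz - target_hz)
        if d < best_d:
            best, best_d = mean, d
        if train.rate_hz < 0.5 * target_hz:
            break  # rate falls with hyperpolarization; no need to go lower
    return float(best)


def synth_recording(spec: SyntheticCellSpec,
                    protocol: CurrentWaveform,
                    init=None) -> VoltageTrace:
    """Emulated current-clamp recording of the cell under ``protocol``.

    The model is integrated at half the sampling interval and decimated to
    ``fs_khz``; Gaussian measurement noise of ``noise_sd_mV`` is added to V.
    """
    dt_rec = 1.0 / spec.fs_khz
    dt_int = dt_rec / 2.0
    trace, train, _ = integrate(spec.params, protocol, init=init, dt=dt_int)
    rng = np.random.default_rng(spec.seed + 777)
    # the formal aEIF spike is instantaneous; a recording shows an action
    # potential peak, emulated as one stereotyped +10 mV sample
    Vfull = trace.V.copy()
    spk_fine = (train.times_ms / dt_int).astype(int)
    Vfull[spk_fine] = 10.0
    V = Vfull[1::2].copy()
    I = trace.I_in[1::2].copy()
    spk_rec = spk_fine // 2
    V[np.minimum(spk_rec, len(V) - 1)] = 10.0
    if spec.noise_sd_mV > 0:
        V += spec.noise_sd_mV * rng.standard_normal(len(V))
    out = VoltageTrace(dt=dt_rec, V=V, I_in=I,
                       meta={"source": "synthetic-recording"})
    if protocol.sigma_samples is not None:
        out.meta["sigma_samples"] = np.repeat(protocol.sigma_samples, 2)[1::2]
    return out


def _checksum(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def fixture_suite(seed: int = 0, *, dyniv_noise_s: float = 20.0,
                  representative: Optional[AEIFParams] = None) -> Dict:
    """Deterministic bundle of the fixtures the analyses consume.

    Contains the representative cell's dynamic-IV noise recording (dual-OU,
    sigma = 153 pA, spontaneously firing hold), its pulse recording
    (0.5 ms, 1 nA) and ramp recording, plus a manifest of checksums.
    Heavier protocol outputs (ISR epochs, PSTH sweeps) are generated on
    demand by their analyses; this bundle covers the fitting pipeline.
    """
    if representative is None:
        representative = representative_cell()
    spec = SyntheticCellSpec(params=representative, seed=seed)
    out: Dict = {"spec": spec}

    noise_proto = dual_ou_current(
        mean=0.0, sigma=153.0, dt=1.0 / spec.fs_khz / 2.0, seed=seed + 1,
        noise_ms=dyniv_noise_s * 1000.0)
    out["dyniv_noise"] = synth_recording(spec, noise_proto)

    pulse_proto = build_protocol("pulse", dt=1.0 / spec.fs_khz / 2.0,
                                 hold=-200.0, amp=1000.0, width_ms=0.5,
                                 t_pulse_ms=500.0, total_ms=800.0)
    out["pulse"] = synth_recording(spec, pulse_proto)

    ramp_proto = build_protocol("ramp", dt=0.1, I_start=-650.0, trials=10)
    out["ramp"] = synth_recording(
        SyntheticCellSpec(params=representative, seed=seed + 2,
                          fs_khz=10.0),
        ramp_proto)

    out["manifest"] = {
        k: _checksum(v.V, v.I_in) for k, v in out.items()
        if isinstance(v, VoltageTrace)
    }
    return out
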