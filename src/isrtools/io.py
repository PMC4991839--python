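"""File formats and reproducible-run configuration.

Traces are TSV with header ``time_ms  V_mV  I_pA`` (uniform time grid;
voltage kept to 1e-4 mV, current to 1e-3 pA), spike trains one time per
line, parameter sets JSON with unit-suffixed keys, run configurations JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .integrator import SpikeTrain, VoltageTrace

__all__ = ["read_trace", "write_trace", "read_spikes", "write_spikes",
           "RunConfig"]

_HEADER = ["time_ms", "V_mV", "I_pA"]


def write_trace(trace: VoltageTrace, path) -> None:
    """Write a trace as TSV (time to 1e-4 ms, V to 1e-4 mV, I to 1e-3 pA)."""
    t = trace.t_ms
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for i in range(trace.n):
            fh.write(f"{t[i]:.4f}\t{trace.V[i]:.4f}\t{trace.I_in[i]:.3f}\n")


def read_trace(path) -> VoltageTrace:
    """Read a TSV trace; validates the header and the uniform time grid."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header:
            raise ValueError(f"{path}: empty trace file")
        cols = header.split("\t")
        missing = [c for c in _HEADER if c not in cols]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing}")
        data = np.loadtxt(fh, delimiter="\t")
    if data.ndim == 1:
        data = data[None, :]
    if len(data) < 2:
        raise ValueError(f"{path}: trace needs >= 2 samples")
    it, iv, ii = (cols.index(c) for c in _HEADER)
    t = data[:, it]
    dts = np.diff(t)
    dt = dts[0]
    bad = np.where(np.abs(dts - dt) > 1e-6)[0]
    if len(bad):
        raise ValueError(
            f"{path}: non-uniform time grid first at row {bad[0] + 3}")
    return VoltageTrace(dt=float(dt), V=data[:, iv], I_in=data[:, ii],
                        meta={"source": str(path)})


def write_spikes(train: SpikeTrain, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# duration_ms\t{train.duration_ms:.4f}\n")
        for t in train.times_ms:
            fh.write(f"{t:.4f}\n")


def read_spikes(path) -> SpikeTrain:
    duration = None
    times = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "duration_ms" in line:
                    duration = float(line.split("\t")[-1])
                continue
            times.append(float(line))
    times = np.asarray(times)
    if duration is None:
        duration = (times[-1] + 1.0) if len(times) else 0.0
    return SpikeTrain(times, duration)


def run_stage(config: "RunConfig") -> dict:
    """Execute one named analysis stage from a config; returns a summary.

    Stages: ``simulate`` (OU-driven integration; writes trace + spikes),
    ``isr-curve`` (stepped-noise tuning curve; writes a TSV table),
    ``hysteresis`` (ramp protocol; writes JSON), ``fi`` (step protocol;
    writes a TSV table).  Outputs are byte-identical across reruns of the
    same config.
    """
    from .params import AEIFParams, representative_cell
    from .stimulus import OUSpec, ou_series
    from .integrator import integrate
    from . import response as _resp
    import numpy as np

    p = (AEIFParams.from_json(config.inputs["params"])
         if "params" in config.inputs else representative_cell())
    pars = config.parameters
    summary = {"stage": config.stage, "seed": config.seed}

    if config.stage == "simulate":
        wf = ou_series(OUSpec(mu=pars.get("mean_pA", -150.0),
                              sigma=pars.get("sigma_pA", 30.0),
                              tau=pars.get("tau_ms", 2.0)),
                       0.1, int(pars.get("duration_ms", 10_000.0) / 0.1),
                       seed=config.seed)
        trace, train, _ = integrate(p, wf)
        write_trace(trace, config.outputs["trace"])
        write_spikes(train, config.outputs["spikes"])
        summary["n_spikes"] = len(train)
    elif config.stage == "isr-curve":
        sigmas = np.asarray(pars.get("sigmas_pA",
                                     np.arange(0.0, 101.0, 10.0).tolist()))
        c = _resp.isr_curve_from_model(
            p, pars.get("mean_pA", -150.0), sigmas,
            reps=int(pars.get("reps", 5)),
            T_ms=pars.get("epoch_ms", 10_000.0), seed=config.seed)
        with open(config.outputs["table"], "w") as fh:
            fh.write("sigma_pA\trate_Hz\tsmoothed_Hz\n")
            for s, r, sm in zip(c.sigma, c.rate, c.smoothed):
                fh.write(f"{s:.1f}\t{r:.4f}\t{sm:.4f}\n")
        summary["sigma_opt_pA"] = c.sigma_opt
    elif config.stage == "hysteresis":
        h = _resp.hysteresis_ramp(p)
        d = {"f_up_Hz": h.f_up, "f_down_Hz": h.f_down, "I_up_pA": h.I_up,
             "I_down_pA": h.I_down, "delta_I_pA": h.delta_I,
             "delta_f_Hz": h.delta_f}
        with open(config.outputs["table"], "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")
        summary.update(d)
    elif config.stage == "fi":
        r = _resp.fi_curve(p)
        with open(config.outputs["table"], "w") as fh:
            fh.write("I_pA\tf_Hz\n")
            for I, f in zip(r["I"], r["f"]):
                fh.write(f"{I:.1f}\t{f:.4f}\n")
        summary["onset_I_pA"] = r["onset_I"]
    else:
        raise ValueError(f"unknown stage {config.stage!r}")
    return summary


@dataclass
class RunConfig:
    """One reproducible analysis stage: name, paths, parameters, seed."""

    stage: str
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    version: str = "isrtools-0.1.0"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        allowed = {"stage", "seed", "inputs", "outputs", "parameters",
                   "version"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
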