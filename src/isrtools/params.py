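"""Adaptive exponential integrate-and-fire (aEIF) model definitions.

The aEIF model describes the membrane potential ``V`` (mV) and an adaptation
current ``w`` (pA) of a spiking neuron:

.. math::

    C \\frac{dV}{dt} &= -g_L (V - E_L) + g_L \\Delta_T
        e^{(V - V_T)/\\Delta_T} - w + I(t) \\\\
    \\tau_w \\frac{dw}{dt} &= a (V - E_L) - w

with the reset rule: when ``V`` exceeds ``V_spike``, a spike is recorded,
``V ← V_r`` and ``w ← w + b``.

Units are fixed throughout the package: mV, ms, pA, nS, pF, so that
``C dV/dt`` is in pA.

This module holds the parameter containers, the right-hand side of the model,
the dimensionless rescaling used to map the bistable (type II) region of
parameter space, the excitability classification, the closed-form rheobase of
the type II model and a two-compartment variant with a passive dendrite.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from typing import Tuple

__all__ = [
    "AEIFParams",
    "RescaledParams",
    "TwoCompartmentParams",
    "aeif_derivatives",
    "two_compartment_derivatives",
    "rescale",
    "classify_excitability",
    "rheobase_up",
    "representative_cell",
]

# JSON keys carry explicit unit suffixes.
_FIELD_KEYS = {
    "C": "C_pF",
    "gL": "gL_nS",
    "EL": "EL_mV",
    "VT": "VT_mV",
    "DeltaT": "DeltaT_mV",
    "a": "a_nS",
    "b": "b_pA",
    "tau_w": "tau_w_ms",
    "Vr": "Vr_mV",
    "Vspike": "Vspike_mV",
}


@dataclass(frozen=True)
class AEIFParams:
    """Biophysical parameter vector of the aEIF neuron.

    Attributes
    ----------
    C : float
        Membrane capacitance (pF).
    gL : float
        Leak conductance (nS).
    EL : float
        Leak reversal potential (mV).
    VT : float
        Threshold potential of the exponential term (mV).
    DeltaT : float
        Spike slope factor (mV).
    a : float
        Subthreshold adaptation conductance (nS).
    b : float
        Spike-triggered adaptation increment (pA).
    tau_w : float
        Adaptation time constant (ms).
    Vr : float
        Post-spike voltage reset (mV).
    Vspike : float
        Spike-cut threshold (mV); crossing it triggers the reset rule.
    """

    C: float
    gL: float
    EL: float
    VT: float
    DeltaT: float
    a: float
    b: float
    tau_w: float
    Vr: float = -60.0
    Vspike: float = 0.0

    def __post_init__(self) -> None:
        if not all(
            math.isfinite(v)
            for v in (self.C, self.gL, self.EL, self.VT, self.DeltaT,
                      self.a, self.b, self.tau_w, self.Vr, self.Vspike)
        ):
            raise ValueError("all aEIF parameters must be finite")
        if self.C <= 0:
            raise ValueError(f"C must be > 0 (got {self.C})")
        if self.gL <= 0:
            raise ValueError(f"gL must be > 0 (got {self.gL})")
        if self.DeltaT <= 0:
            raise ValueError(f"DeltaT must be > 0 (got {self.DeltaT})")
        if self.tau_w <= 0:
            raise ValueError(f"tau_w must be > 0 (got {self.tau_w})")
        if self.Vr >= self.Vspike:
            raise ValueError(
                f"Vr ({self.Vr}) must be below Vspike ({self.Vspike})"
            )

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/gL (ms)."""
        return self.C / self.gL

    def with_(self, **kw) -> "AEIFParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {_FIELD_KEYS[k]: v for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "AEIFParams":
        inv = {v: k for k, v in _FIELD_KEYS.items()}
        kwargs = {}
        for key, val in d.items():
            if key not in inv:
                raise ValueError(f"unknown parameter key {key!r} "
                                 "(expected unit-suffixed keys like 'C_pF')")
            kwargs[inv[key]] = float(val)
        return cls(**kwargs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "AEIFParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def representative_cell() -> AEIFParams:
    """Parameters of the bundled representative Purkinje cell fit."""
    txt = resources.files("isrtools.data").joinpath(
        "representative_cell.json").read_text()
    return AEIFParams.from_dict(json.loads(txt))


@dataclass(frozen=True)
class RescaledParams:
    """Dimensionless form of the aEIF model.

    ``T = tau_w/tau_m`` and ``A = a/gL`` are the two parameters that decide
    excitability class and the extent of the bistable region; ``Ibar``,
    ``bbar`` and ``Vr_bar`` are the input, adaptation reset and voltage reset
    in units of ``gL * DeltaT`` and ``DeltaT``.
    """

    T: float
    A: float
    Ibar: float
    bbar: float
    Vr_bar: float

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be > 0")
        if self.A < 0:
            raise ValueError("A must be >= 0")

    def restore(self, anchor: AEIFParams) -> Tuple[AEIFParams, float]:
        """Invert the rescaling against an anchor (C, gL, EL, VT, DeltaT).

        Returns the parameter set (a, tau_w, b, Vr rebuilt from the
        dimensionless values) and the dimensional input current in pA.
        """
        gL, DT, VT, EL = anchor.gL, anchor.DeltaT, anchor.VT, anchor.EL
        a = self.A * gL
        tau_w = self.T * anchor.tau_m
        b = self.bbar * gL * DT
        Vr = self.Vr_bar * DT + VT
        I = (self.Ibar - (1.0 + self.A) * (EL - VT) / DT) * gL * DT
        return anchor.with_(a=a, tau_w=tau_w, b=b, Vr=Vr), I


def rescale(params: AEIFParams, I: float) -> RescaledParams:
    """Map an aEIF parameter set and input current to dimensionless form."""
    gL, DT = params.gL, params.DeltaT
    A = params.a / gL
    T = params.tau_w / params.tau_m
    Ibar = I / (gL * DT) + (1.0 + A) * (params.EL - params.VT) / DT
    bbar = params.b / (gL * DT)
    Vr_bar = (params.Vr - params.VT) / DT
    return RescaledParams(T=T, A=A, Ibar=Ibar, bbar=bbar, Vr_bar=Vr_bar)


def aeif_derivatives(
    state: Tuple[float, float], params: AEIFParams, I: float
) -> Tuple[float, float]:
    """Right-hand side of the aEIF model at ``state = (V, w)``.

    Returns ``(dV/dt, dw/dt)`` in (mV/ms, pA/ms).
    """
    V, w = state
    if not (math.isfinite(V) and math.isfinite(w) and math.isfinite(I)):
        raise ValueError("state and input must be finite")
    dV = (
        -params.gL * (V - params.EL)
        + params.gL * params.DeltaT * math.exp((V - params.VT) / params.DeltaT)
        - w
        + I
    ) / params.C
    dw = (params.a * (V - params.EL) - w) / params.tau_w
    return dV, dw


def classify_excitability(params: AEIFParams) -> str:
    """Classify the model as ``"type_I"`` or ``"type_II"``.

    The model has type II excitability (firing onset at nonzero frequency,
    rest state destabilized through an Andronov-Hopf bifurcation) when
    ``a/gL > tau_m/tau_w``; otherwise onset is through a saddle-node
    (type I).  The measure-zero boundary case is classified type_I with a
    warning.
    """
    ratio_A = params.a / params.gL
    ratio_T = params.tau_m / params.tau_w
    if ratio_A > ratio_T:
        return "type_II"
    if ratio_A == ratio_T:
        warnings.warn(
            "a/gL == tau_m/tau_w: degenerate excitability boundary, "
            "classifying as type_I",
            stacklevel=2,
        )
    return "type_I"


def rheobase_up(params: AEIFParams) -> float:
    """Closed-form rheobase current I_up (pA) of the type II aEIF model.

    I_up is the minimal constant input at which the rest state can no longer
    hold the trajectory (the Andronov-Hopf point of the subthreshold system):

    ``I_up = (gL+a) [VT - EL - DT + DT log(1 + tau_m/tau_w)]
    + DT gL (a/gL - tau_m/tau_w)``.

    Only valid for type II parameter sets; raises ``ValueError`` otherwise.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if classify_excitability(params) != "type_II":
            raise ValueError(
                "rheobase closed form requires type II excitability "
                "(a/gL > tau_m/tau_w)"
            )
    gL, a, DT = params.gL, params.a, params.DeltaT
    r = params.tau_m / params.tau_w
    return (gL + a) * (
        params.VT - params.EL - DT + DT * math.log1p(r)
    ) + DT * gL * (a / gL - r)


@dataclass(frozen=True)
class TwoCompartmentParams:
    """aEIF soma coupled to a passive dendritic compartment.

    The soma obeys the aEIF equations plus a coupling current
    ``gc (Vd - V)``; the dendrite is a passive RC compartment:
    ``Cd dVd/dt = -gLd (Vd - EL) + gc (V - Vd)``.
    """

    soma: AEIFParams
    gc: float
    Cd: float
    gLd: float

    def __post_init__(self) -> None:
        if self.gc <= 0:
            raise ValueError("gc must be > 0")
        if self.Cd <= 0:
            raise ValueError("Cd must be > 0")
        if self.gLd < 0:
            raise ValueError("gLd must be >= 0")


def two_compartment_derivatives(
    state: Tuple[float, float, float],
    params: TwoCompartmentParams,
    I: float,
) -> Tuple[float, float, float]:
    """Right-hand side ``(dV/dt, dw/dt, dVd/dt)`` of the two-compartment model."""
    V, w, Vd = state
    s = params.soma
    dV, dw = aeif_derivatives((V, w), s, I)
    dV += params.gc * (Vd - V) / s.C
    dVd = (-params.gLd * (Vd - s.EL) + params.gc * (V - Vd)) / params.Cd
    return dV, dw, dVd
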