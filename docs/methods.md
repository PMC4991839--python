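# Methods

## The model

`isrtools` simulates and analyzes an adaptive exponential integrate-and-fire
(aEIF) neuron parameterized for a cerebellar Purkinje cell:

    C dV/dt   = -gL (V - EL) + gL ΔT exp((V - VT)/ΔT) - w + I(t)
    τw dw/dt  = a (V - EL) - w
    if V > Vspike:  V ← Vr,  w ← w + b

Units are fixed to {mV, ms, pA, nS, pF}.  The bundled representative cell is

    C = 268 pF, gL = 8.47 nS, EL = -51.31 mV, VT = -53.23 mV, ΔT = 0.85 mV,
    a = 37.79 nS, b = 441.12 pA, τw = 20.76 ms, Vspike = 0 mV.

Note EL > VT: at zero input the subthreshold flow has no fixed point and the
cell fires spontaneously, as Purkinje cells do.  With `a/gL > τm/τw`
(τm = C/gL) the model has type II excitability: the rest state, where it
exists, is a focus that loses stability through a subcritical Andronov-Hopf
bifurcation, and over an interval of holding currents a stable rest state
coexists with the spiking limit cycle.  For the representative cell the
closed-form rheobase (the Hopf current) is I_up = -70.6 pA, the subthreshold
fold is at -61.4 pA, and the spiking limit cycle persists down to
I_down ≈ -166 pA; -150 pA, the operating point of all noise analyses, sits
inside the bistable interval.

### The voltage reset

Vr is the one dynamical parameter with no published value.  It matters: the
bistability requires the post-spike reset point (Vr, w + b) to land outside
the rest state's basin of attraction.  Because EL > VT here, resetting to EL
(a common convention) puts the trajectory back inside the basin and the σ=0
limit cycle at -150 pA dies — no bistability and no inverse stochastic
resonance at all.  A scan shows that any Vr in roughly [-62, -52] mV
reproduces the reported phenomenology (sustained σ=0 firing at -150 pA, rest
at -200 pA, firing at -100 pA, noise-optimal suppression near σ = 30 pA);
the package default is Vr = -60 mV, configurable in `AEIFParams`.

## Numerics

Integration is forward Euler at dt = 0.1 ms (kernels JIT-compiled with
numba); synthetic recordings use dt = 0.01 ms and are decimated to the
50 kHz acquisition rate.  Halving dt changes noise-free 1 s spike counts by
at most one.  Spike times use the left-edge convention (the sample at which
V first exceeds Vspike); the reset applies in the same step, with no
refractory hold.  OU noise is generated with the exact AR(1) update
`x ← μ + (x-μ)e^{-dt/τ} + σ√(1-e^{-2dt/τ}) z`, so stationary mean, variance
and autocorrelation are exact at any step.  Biexponential synaptic events
(τ1 = 1.5 ms rise, τ2 = 10 ms decay) are normalized by K(τ1, τ2) so a single
event peaks exactly at its nominal amplitude.

## Phase-plane analysis and the probability of spiking

Fixed points are roots of the reduced nullcline equation, located by a dense
sign scan plus Brent refinement and classified by the analytic Jacobian.
The Hopf current is found by bisection on the leading eigenvalue's real
part.  The rest basin is computed on a (V, w) grid (default 0.25 mV × 5 pA
over [-90, 0] mV × [-400, 1200] pA) by noise-free integration: a cell
belongs to the basin iff its trajectory produces no spike within 500 ms and
ends near the fixed point.  The probability of spiking under noise is
P_sp = 1 - P_r, where P_r is the fraction of integration time the
trajectory's (V, w) lies inside the basin (instantaneous nearest-cell
membership); by convention P_sp = 1 where no stable fixed point exists.

The PSTH ("probability of spiking" per 20 ms bin across sweeps) reports
basin-state occupancy by default rather than spike occurrence.  The two
differ materially: the up-state firing rate of this cell (~20 Hz, ISI
~50 ms) leaves most 20 ms bins of an up-state sweep without a spike, so
spike-occurrence probabilities saturate near 0.4 even at full up-state
occupancy, whereas the state-occupancy baseline at σ = 60 pA is ≈ 0.45 — the
regime where noise randomly toggles the two states.  A
`probability="spike"` variant is available.  The synaptic stimulus in PSTH
protocols arrives at t = 3 s of 6 s sweeps; the baseline is averaged over
1–3 s so the from-rest transient (≈0.5 s at σ = 60 pA) has equilibrated.

### Ramp onset vs rheobase

The quasi-static definition of I_up — the minimal constant current that
elicits a spike from rest — converges to the closed form to < 1 pA
(bisection over step protocols).  The first-spike current of a noise-free
*ramp*, however, does not: the trajectory tracks the focus beyond the Hopf
point (delayed, or memory, Hopf passage) and escapes only near the
subthreshold fold, ≈ 8 pA above the rheobase, at every ramp speed tested
(0.9, 0.09 and 0.009 nA/s).  Any noise collapses the delay, which is why
ramp experiments on real cells do not show it.  The hysteresis analysis
therefore reports ramp onsets as measured, and the bistable-interval
analysis uses the step-protocol definitions.

## The modified dynamic I-V pipeline

Stages (each exposed separately, each implementing the classical formula):

1. **Capacitance** minimizes the count-weighted within-bin variance of
   `I_in/Ce - dV/dt` (grid 50–600 pF at 1 pF plus golden-section
   refinement; the objective is quadratic in 1/Ce, so per-bin moments make
   each evaluation O(bins)).
2. **Dynamic I-V curve**: `I_m = I_in - Ce dV/dt` (central differences at
   the native 50 kHz), post-spike windows (peak to +10 ms) excluded, means
   per 1 mV voltage bin (bins with < 50 samples dropped).
3. **EIF fit** of `-I_dyn/C` to `F(V) = (EL - V + ΔT e^{(V-VT)/ΔT})/τm`
   (weighted nonlinear least squares).
4. **Pulse time constant**: biexponential fit of the relaxation after a
   0.5 ms, 1 nA pulse.  For a single-compartment cell with strong slow
   adaptation the rest state is a focus and the relaxation *rings*; a
   damped-cosine branch handles that case.  For the two-compartment variant
   the two real constants match the eigenvalues of the passive system.
5. **Subthreshold adaptation**: a = (linear-window slope of the curve) − gL.
6. **Spike-triggered adaptation**: `w_spike = I_in - C dV/dt -
   (gL+a)(V-EL)`, binned by time since the last spike and fitted with
   `b e^{-t/τw}`.

**Why a refinement stage exists.**  Stages 3 and 5 assume the adaptation
current tracks the voltage instantaneously (`E[w|V] = a(V-EL)`).  With
τw ≥ 15 ms and input correlation times of 3/10 ms that is far from true: the
conditional-mean slope of w against V is attenuated by a factor
κ = Cov(w, V)/(a·Var V) ≈ 0.3 for the representative cell (computable from
the stationary Lyapunov equation of the linearized system), so the raw
curve slope measures gL_eff + κa, not gL + a, and EL, τm and a inherit the
bias.  The capacitance stage is similarly biased by the within-bin
covariance between the input and the adaptation current.  `fit_full`
therefore finishes with a self-consistent refinement: the adaptation
current is reconstructed sample-by-sample from the measured voltage and
spike times (integrating τw dw/dt = a(V-EL) - w with +b kicks at spikes),
and (gL, EL, VT, ΔT, a, τw, b) are fitted by least squares on the full
current-balance residual using raw, unfiltered signals — the large
differentiation noise is independent of every regressor and averages out,
whereas low-pass filtering distorts the exponential term.  The fit is
multi-started over τw (the least identifiable direction, because the 10 ms
post-spike exclusion hides the early decay) and alternated with an
adaptation-corrected capacitance estimate; since that alternation has no
joint objective, every intermediate (θ, C) pair is kept and the winner is
chosen by the residual of the adaptation-corrected bin-mean I-V curve,
a criterion immune to the errors-in-variables penalty on dV/dt.  Vr is
estimated as the median voltage one sample after each spike.

On synthetic ground-truth recordings (20 s dual-OU injections at σ=153 pA,
holding mean adapted per cell to ≈25 Hz firing as in the experiments,
0.2 mV measurement noise) the full pipeline recovers parameters with median
relative errors of ~1–2% (C, EL, VT, a, b, τw) and ~10% (ΔT) across a
20-cell population sampled from the published statistics, with no
type II → type I classification flips.

## Synthetic data

No recordings are deposited, so every analysis is exercised on emulated
recordings: ground-truth aEIF cells integrated at fine step, decimated to
50 kHz, with 0.2 mV white measurement noise on V (the injected current is
stored losslessly).  Because the formal aEIF spike is instantaneous (the
Euler overshoot is never stored), a stereotyped +10 mV sample is pasted at
each spike time so that threshold-crossing spike detection sees the action
potentials a real recording would show.  Population cells are drawn
independently per parameter from truncated normals matching the published
mean ± SD (C 195.4 ± 53.3 pF, τm 4.4 ± 1.2 ms with gL = C/τm,
EL −51.9 ± 1.9 mV, VT −54.1 ± 2.3 mV, ΔT 1.0 ± 0.2 mV, a 36.1 ± 6.3 nS,
b 408 ± 128 pA, τw 14.8 ± 6.3 ms), redrawn until type II (all recorded cells were);
parameter covariances are not published and are ignored.  What passing
recovery tests show is therefore internal consistency of the estimators on
model-matched data with instrument-like noise — not robustness to dendrites,
channel noise, electrode artifacts or model mismatch, none of which the
generator emulates.

## Information transfer

Spike trains are binarized in 25 ms bins (1 = at least one spike).  Entropy
rates use context tree weighting with depth D = 40 bins (a 1 s context): a
sparse suffix tree whose nodes hold Krichevsky-Trofimov estimators, mixed
1/2-1/2 with their children's product, all in log domain; the m-ary KT form
serves the 4-symbol joint alphabet.  MI = H(X) + H(Y) − H(X,Y), converted
to bits/s by the bin width.  Against analytic Bernoulli and Markov sources
the estimator is accurate to < 0.005 bits/symbol at n = 1e5; MI estimates on
pipeline data change by < 5% when D doubles.  Small negative MI estimates
(independent trains) are reported raw, with a clipped-at-zero summary
accessor.

## Problem sizes and defaults in the shipped analyses

ISR curves: σ ∈ 0–100 pA in 10 pA steps, 20 epochs × 30 s each, Gaussian
smoothing of width one step.  PSTHs: 1000 sweeps × 6 s, 20 ms bins.
Input-output curves: amplitudes 0–150 pA in 12.5 pA steps, 500–700 sweeps
each; threshold = smallest amplitude whose peak exceeds baseline by > 0.1,
saturation = smallest amplitude beyond which successive peak changes stay
below 5% of the range (both exposed in the API).  The threshold rule is
stricter than a visual "lift-off" reading of a response curve: on this
model the transition probability at 50 pA is ≈ 0.07, so the rule reports
62.5 pA even though amplitudes below 50 pA indeed evoke essentially no
response.  MI sweeps: 300 s × 3 repeats per noise amplitude (the full-length
protocol of 1000 s × 10 changes the argmax by nothing but costs an order of
magnitude more).  Parameter recovery: 20 cells × 20 s recordings.

## Known limitations

- The two-compartment variant uses a standard resistive coupling with the
  capacitance/leak split between compartments exposed as configuration.
- The continuous-amplitude ISR protocol needs the amplitude ramp to be slow
  relative to the 200 ms analysis windows to resolve the curve; at the
  default 0.5 nA/s the amplitude moves 100 pA per window and the per-window
  amplitude labels are coarse.
- CTW is pure Python (dict-based); ~40 µs per symbol·level.  Fine for the
  shipped analyses, slow for very long trains.
- Basin membership during noisy simulation uses the basin of the *mean*
  current; instantaneous membership during large noise excursions is an
  approximation inherited from the definition of P_r.
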