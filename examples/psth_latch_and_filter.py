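"""Noise sets the lifetime of stimulus-evoked firing.

From the rest state, a single 100 pA biexponential synaptic input switches
the model into its firing state.  How long the firing persists depends on
the background noise amplitude: at 10 pA the model latches (probability
stays up), at 30 pA (the ISR optimum) the evoked firing decays within about
a second, and at 60 pA random switching dominates and the baseline sits
near one half.
"""

import isrtools as it

p = it.representative_cell()
basin = it.rest_basin(p, -150.0)

for sigma in (10.0, 30.0, 60.0):
    r = it.psth(p, Am=100.0, sigma=sigma, sweeps=200, seed=2, basin=basin)
    post = r.p[r.t_centers_ms >= r.t_st_ms]
    line = (f"sigma={sigma:5.0f} pA: baseline={r.baseline:.3f}  "
            f"peak={post.max():.3f}  end={post[-10:].mean():.3f}")
    try:
        d = it.decay_time_constant(r)
        tau = "infinite" if d["infinite"] else f"{d['tau_s']:.2f} s"
        line += f"  decay tau={tau}"
    except ValueError:
        pass
    print(line)
print("\n(baseline/peak/end are spiking-state probabilities per 20 ms bin;")
print(" the stimulus arrives at t = 3 s of 6 s sweeps)")
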