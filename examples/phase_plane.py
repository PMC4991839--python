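"""Bistability in the (V, w) phase plane.

At a holding current inside the bistable range the subthreshold flow has a
stable focus (the rest state) and a saddle; the rest state's basin of
attraction is a drop-shaped region.  The post-spike reset lands outside the
basin, which is why spiking is self-sustaining.  The rest state loses
stability through an Andronov-Hopf bifurcation exactly at the closed-form
rheobase current.
"""

import isrtools as it

p = it.representative_cell()
I = -150.0

for fp in it.find_fixed_points(p, I):
    ev = fp.eigenvalues[0]
    print(f"fixed point at V={fp.V:7.2f} mV, w={fp.w:8.1f} pA: {fp.kind}"
          f"  (eigenvalue {ev.real:+.4f} {abs(ev.imag):+.4f}i /ms)")

basin = it.rest_basin(p, I)
frac = basin.mask.mean()
print(f"\nrest basin at I={I:.0f} pA occupies {100 * frac:.1f}% of the "
      f"scanned (V, w) grid")

V0, w0 = it.limit_cycle_state(p, I)
print(f"post-spike reset point ({V0:.1f} mV, {w0:.0f} pA) inside basin? "
      f"{basin.contains(V0, w0)}")

h = it.hopf_scan(p)
print(f"\nHopf bifurcation at I = {h.I:.2f} pA "
      f"(imaginary part {h.omega:.3f} rad/ms)")
print(f"closed-form rheobase I_up = {it.rheobase_up(p):.2f} pA")
lo, hi = it.bistable_range(p)
print(f"bistable interval (step protocols): [{lo:.0f}, {hi:.0f}] pA")
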