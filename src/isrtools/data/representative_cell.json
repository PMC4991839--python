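{
  "C_pF": 268.0,
  "gL_nS": 8.47,
  "EL_mV": -51.31,
  "VT_mV": -53.23,
  "DeltaT_mV": 0.85,
  "a_nS": 37.79,
  "b_pA": 441.12,
  "tau_w_ms": 20.76,
  "Vr_mV": -60.0,
  "Vspike_mV": 0.0
}
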