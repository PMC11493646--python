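name: KV14_NTYPE_LIKE
note: >-
  Synthetic parameter set for an N-type (ball-and-chain) inactivating
  Kv1.4-like subunit paired with the KV11_LIKE non-inactivating partner
  rates. These numbers are NOT the published Kv1.4 model parameters; they
  were chosen so that (a) the activation midpoint sits near -32 mV,
  (b) activation gating is at least 100x faster than inactivation over
  -60..50 mV (the quasi-steady-state regime), and (c) ball binding and
  unbinding occur on the multi-second timescale typical of N-type
  inactivation. aI and bI are voltage-insensitive constants.
plain:
  a2: {form: exponential, m: 0.5, n: 0.04}
  b2: {form: exponential, m: 0.06, n: -0.03}
inactivating:
  a1: {form: exponential, m: 0.6, n: 0.035}
  b1: {form: exponential, m: 0.08, n: -0.028}
  aI: {form: constant, value: 1.2e-4}
  bI: {form: constant, value: 1.3e-4}
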