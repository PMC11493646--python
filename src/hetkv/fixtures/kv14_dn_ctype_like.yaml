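name: KV14_DN_CTYPE_LIKE
note: >-
  Synthetic parameter set for a C-type inactivating subunit (a stand-in
  for an N-terminus-deleted Kv1.4-like subunit) paired with the KV11_LIKE
  non-inactivating partner rates. These numbers are NOT the published
  Kv1.4dN model parameters; they were chosen so that (a) the activation
  midpoint sits near -32 mV, (b) per-subunit C-type inactivation at
  +50 mV proceeds with a time constant of about one second, and (c) the
  per-subunit inactivated fraction at +50 mV is modest, giving the
  near-linear per-subunit dose response characteristic of independent
  C-type gates. aI and bI are voltage-insensitive constants.
plain:
  a2: {form: exponential, m: 0.5, n: 0.04}
  b2: {form: exponential, m: 0.06, n: -0.03}
inactivating:
  a1: {form: exponential, m: 0.6, n: 0.035}
  b1: {form: exponential, m: 0.08, n: -0.028}
  aI: {form: constant, value: 7.5e-5}
  bI: {form: constant, value: 1.0e-3}
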