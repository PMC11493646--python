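name: KV11_LIKE
note: >-
  Synthetic parameter set for a non-inactivating Kv1.1-like subunit.
  These numbers are NOT the published Kv1.1 model parameters; they were
  chosen so that the single-subunit activation midpoint (where a2 = b2)
  sits near -30 mV with gating time constants of a few milliseconds,
  i.e. in the qualitative regime of delayed-rectifier Kv channels.
plain:
  a2: {form: exponential, m: 0.5, n: 0.04}
  b2: {form: exponential, m: 0.06, n: -0.03}
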