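# C-type homomer with an explicit inline rate set and a fit section:
# `hetkv fit --config examples/ctype_fit.yaml --target <dir> --out <dir>`
# fits (m1, n1, m2, n2, aI, bI) to target protocol CSVs;
# `hetkv run` performs a seeded synthetic-target self-fit instead.
family: c_type
inactivating: 4
rates:
  inactivating:
    a1: {form: exponential, m: 0.6, n: 0.035}
    b1: {form: exponential, m: 0.08, n: -0.028}
    aI: {form: constant, value: 7.5e-5}
    bI: {form: constant, value: 1.0e-3}
fit:
  maxiter: 80
  popsize: 10
seed: 17
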