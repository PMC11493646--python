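# 2 N-type : 2 non-inactivating heteromer, synthetic fixture rates,
# default clamp protocols.
family: n_type
inactivating: 2
fixture: KV14_NTYPE_LIKE
reduction: qss
seed: 0
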