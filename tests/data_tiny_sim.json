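{
 "n_founder_females": 25,
 "n_founder_males": 20,
 "n_years": 12,
 "carrying_capacity": 25,
 "n_immigrants": 6,
 "seed": 1
}
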