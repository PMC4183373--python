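{
 "sim": {"dt": 0.2, "n_steps": 400000, "preheat_steps": 10000,
         "n_realizations": 5, "sample_stride": 25, "seed": 7},
 "clamp_len": 10,
 "n_pc": 3,
 "n_bins": 6
}
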