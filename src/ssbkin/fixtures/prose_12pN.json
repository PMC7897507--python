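{
  "label": "prose_12pN",
  "force_pN": 12.0,
  "k_b_per_nM_s": 0.18,
  "rates_s_inv": {
    "k_off": 0.017,
    "k_w": 1.8,
    "k_unw": 0.0,
    "k_off_stim": 0.1,
    "k_unw_stim": 0.10
  },
  "footprints_nt": {"n_b": 8, "n_w": 17},
  "compaction_nm_per_nt": {"x_b": 0.0159, "x_w": 0.083}
}
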