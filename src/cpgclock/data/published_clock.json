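{
  "global_intercept": -4.38996,
  "global_slope": 2.57328,
  "enet_intercept": 0.0,
  "selected_lambda": 0.16539,
  "weights": {},
  "class_coefficients": {
    "Aves": {"a": -0.90323, "b": 2.14857},
    "Fish": {"a": 2.14632, "b": -6.58228},
    "Mammalia": {"a": -0.92888, "b": 2.33508},
    "Reptilia": {"a": -0.48958, "b": 1.17281}
  },
  "promoter_order": []
}
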