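{
  "alcohol": {"b_intercept": 1.361, "b_psych": -2.421, "b_psych_age": 0.014},
  "drunkenness": {"b_intercept": 2.092, "b_psych": -0.9, "b_psych_age": 0.0},
  "vaping": {"b_intercept": 1.684, "b_psych": -0.801, "b_psych_age": 0.0}
}
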