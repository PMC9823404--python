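{
  "response": "naproxen_aspirin",
  "intercept": 0.626,
  "linear": [0.204, 0.13, -0.318, 0.49],
  "quadratic": [-0.014, -0.125, -0.007, -0.055],
  "interaction": [-0.144, 0.201, 0.296, 0.242, 0.377, -0.554]
}
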