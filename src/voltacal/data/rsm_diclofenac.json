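{
  "response": "diclofenac",
  "intercept": 1.06,
  "linear": [0.069, 0.278, -0.539, 0.613],
  "quadratic": [-0.393, -0.353, -0.153, 0.01],
  "interaction": [0.105, 0.123, 0.156, 0.223, 0.373, -0.885]
}
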