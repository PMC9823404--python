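{
  "response": "paracetamol",
  "intercept": 1.747,
  "linear": [0.22, 0.352, -0.935, 1.082],
  "quadratic": [-0.476, -0.431, -0.308, -0.012],
  "interaction": [-0.309, 0.211, 0.209, 0.297, 0.66, 1.507]
}
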