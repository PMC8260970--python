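# Full-pipeline config: simulated cirrhosis-like cohort, both horizons.
seed: 1
group: cirrhosis          # cirrhosis | compensated | decompensated | fibrosis
simulate:
  n: 2592
  # optional overrides, e.g.
  # link: {shape: sigmoid, params: {amplitude: 2.8, center: 15.0, scale: 3.0}}
  # baseline_hazard: 2.1346e-3
horizons: [28, 90]
grid_step: 0.1
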