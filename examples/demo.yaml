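# Small demo configuration for `fowlplan run-all --config examples/demo.yaml`
# (completes in well under a minute on one CPU).
dataset:
  n_batches: 2
  n_days: 40
  breeds: [guzao]
  batch_start_dates: ["2024-11-05", "2024-11-12"]
schedule:
  tolerance_g: 10.0
  max_iterations: 20
  daily_min_g: 10.0
  daily_max_g: 250.0
  max_rel_change: 0.10
  gain_clip_g: [0.0, 80.0]
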