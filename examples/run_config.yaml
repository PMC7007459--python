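# Minimal end-to-end pipeline configuration.
# Run:  dancehar run --config examples/run_config.yaml --out runs/demo
seed: 7
out_dir: runs/demo
data_dir: null            # null -> simulate a cohort first
generator:
  n_participants: 3
  seed: 0                 # overridden by a seed derived from the global seed
  effect_scale: 1.0
  noise_sd: 0.05
  participant_variability: 0.15
  transition_fraction: 0.4
  include_sync_prelude: true
still_threshold: 0.02     # g
still_min_duration: 4.0   # s
window: 100               # frames (1 s at 100 Hz)
overlap_fraction: 0.75
model:
  conv1_filters: 8
  conv2_filters: 16
  dense_units: 64
  epochs: 6
  batch_size: 64
  learning_rate: 0.002
  class_weighting: false
levels: [1]
transitions_variants: [false]
evaluation: loocv         # or: ablation
locations: all
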