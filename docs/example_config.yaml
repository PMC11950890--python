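# Example configuration for the `fillstates` CLI.
# Every key is optional; omitted keys fall back to package defaults.

phantom:            # synth.PhantomConfig fields
  shape: [32, 32, 32]
  n_controls: 40
  effect_size: 5.0
  group_fractions: {CN: 0.02, SCD: 0.10, MCI: 0.30, dementia: 0.55}

group_sizes: {CN: 30, SCD: 30, MCI: 30, dementia: 30}

pipeline:           # pipeline.PipelineConfig fields
  cutoffs: {amyloid: 1.65, tau: 1.65, neurodegeneration: -1.65}
  directions: {amyloid: greater, tau: greater, neurodegeneration: less}
  amyloid_suvr_threshold: 1.11   # conventional florbetapir literature value
  reflect_sqrt_scores: true
  bonferroni_m: 3

estimator:          # cnn.EstimatorConfig fields
  channels: [8, 16, 32, 32]
  epochs: 40
  lr: 0.003
  val_fraction: 0.3
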