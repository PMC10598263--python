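# Smoke-scale experiment config for `hncnet run` / `hncnet ablate-window`.
# Flags mirror the package defaults; scale n_patients and max_epochs up
# for real studies.
seed: 1
outcome: DM
split_mode: cohort_split
cohort:
  n_patients: 60
  prevalence: 0.3
  effect_size: 2.0
  censoring_fraction: 0.1
  time_frame_days: 730
  seed: 0            # overridden by the master seed's phantom substream
preprocess:
  window: {level: 125, width: 350}
  gaussian_sigma: 1.0
  crop_size: 180
train:
  learning_rate: 0.05
  momentum: 0.9
  l2_lambda: 1.0e-4
  batch_size: 64
  max_epochs: 20
  early_stop_train_auc: 0.95
  w_pos: 3.7
  w_neg: 0.7
  seed: 0            # overridden by the master seed's training substream
selection:
  initial_gap_threshold: 0.05
  escalation_step: 0.01
  mode: gap_constrained
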