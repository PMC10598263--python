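# Versioned architecture of the compact outcome-prediction CNN.
# Three conv blocks (conv -> max-pool -> leaky ReLU) map the 180x180
# single-channel input to a 4x4x32 embedding (512 flat features); four
# fully connected layers (linear -> leaky ReLU -> dropout, the last one
# linear only) reduce them to a single logit read through a sigmoid.
# Total trainable parameters: 85,505.
name: compact-hnc-cnn
version: 1
input:
  height: 180
  width: 180
  channels: 1
conv_blocks:
  - {filters: 8, kernel: 3, stride: 1, pool: 3}
  - {filters: 16, kernel: 3, stride: 1, pool: 3}
  - {filters: 32, kernel: 3, stride: 1, pool: 4}
fc_sizes: [128, 96, 16, 1]
leaky_slope: 0.01
dropout_p: 0.25
init: he_uniform_fan_in
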