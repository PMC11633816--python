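# Case-study-scale grid: five generic axes (72 combinations) crossed with
# loss-specific sub-grids. Only the combo-loss weights are pre-filled;
# extend the conditional section with your own loss-parameter candidates.
base:
  learning_rate: [0.001, 0.005, 0.01]
  dropout: [0.1, 0.3, 0.5]
  optimizer: [adam, rmsprop]
  batch_normalization: [true, false]
  augmentation: [true, false]
  loss_function: [ComboLoss, RFLoss]
conditional:
  ComboLoss:
    w_cce: [0.05, 0.20]
  RFLoss:
    beta: [0.5, 1.0, 2.0]
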