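# 16-trial planted-effect demonstration grid for the phantom cohort:
# batch_normalization is the planted dominant axis; the other axes sit in
# the reference learner's inert regimes (see docs/methods.md).
base:
  learning_rate: [0.01, 0.02]
  dropout: [0.0, 0.3]
  optimizer: [adam, weighted_adam]
  batch_normalization: [true, false]
conditional: {}
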