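# Reference run configuration. Every key is optional; omitted keys take
# the documented defaults (an empty file is valid). Keys mirror the
# GeneratorConfig / PreprocessParams / ModelConfig / TrainConfig fields.

generator:
  # six activity classes with distinct fundamentals (Hz) below the cutoff
  seed: 1
  n_sessions: 12
  segments_per_session: 3
  noise_sd: 0.15

preprocess:
  fs_preset: benchmark   # benchmark = 20 Hz (10 s windows); hardware = 100 Hz
  cutoff: 2.5
  T: 200
  stride: 100
  norm_scope: train      # leak-free z-scoring; "global" fits on all data

model:
  d_model: 128
  n_layers: 2
  h: 4
  d_ff: 256
  kernel_set: [1, 3, 5, 7]
  c_attn: 8
  dropout: 0.1

train:
  learning_rate: 0.001
  batch_size: 64
  epochs: 100
  patience: 10
  folds: 5
  seed: 1
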