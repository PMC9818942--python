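# Desk-scale experiment: one-CPU run in minutes.
# 200 synthetic images, stride-4 delta maps, 200 training iterations.
transform: contourlet
model: riig
weighting: correlated
window: 13
stride: 4
classifier: cnn
n_per_class: 100
image_size: 256
n_augment: 2
max_shift: 11
training:
  batch_size: 16
  learning_rate: 0.0005
  iterations: 200
  warmup_iterations: 0
  test_fraction: 0.1
  seed: 0
out_dir: runs/desk
seed: 0
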