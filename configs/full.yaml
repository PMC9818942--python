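# Full-scale settings: stride-1 delta maps, batch 60, lr 0.01,
# 4000 Adam iterations.  Expect hours on one CPU; point image_dir at a
# directory of labelled B-mode images (benign_*.png / malignant_*.png)
# to run on real data instead of the synthetic generator.
transform: contourlet
model: riig
weighting: correlated
window: 13
stride: 1
classifier: cnn
n_per_class: 1000
image_size: 256
n_augment: 3
max_shift: 11
training:
  batch_size: 60
  learning_rate: 0.01
  iterations: 4000
  test_fraction: 0.1
  seed: 0
out_dir: runs/full
seed: 0
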