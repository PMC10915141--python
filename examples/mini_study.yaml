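# Desk-scale study recipe: three training regimes x five seeds on the
# 4-class shape x texture corpus, with the full evaluation battery.
# Run with:
#   python -c "import blurvision as bv; bv.run_experiment(bv.pipeline.load_run_config('examples/mini_study.yaml'))"
# Expect ~45 minutes on one CPU; outputs land under runs/mini_study as CSV
# tables (one per regime x seed x stage) plus a JSON manifest.
dataset:
  n_shape_classes: 4
  n_texture_classes: 4
  image_size: 64
  samples_per_class: 20
  seed: 100
regimes: [clear, weak_blur, strong_blur]
stages: [train, tuning, shape_bias, robustness]
seeds: [0, 1, 2, 3, 4]
epochs: 80
n_conflict_per_pair: 3
robustness_kinds: [gaussian_noise, defocus_blur, pixelate]
out_dir: runs/mini_study
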