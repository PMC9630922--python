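# Small end-to-end run: cordmaskvar run --config examples/demo.yaml
out_dir: results/demo
n_perm: 500
study:
  n_datasets: 6
  grid_shape: [64, 44, 12]
  act_extent: [3, 9]
  master_seed: 7
  rater_models:
    - {name: expert, bias_voxels: 0, flip_rate: 0.02, slice_jitter_mm: 0.0}
    - {name: trainee, bias_voxels: 0, flip_rate: 0.08, slice_jitter_mm: 0.25}
    - {name: generous, bias_voxels: 1, flip_rate: 0.06, slice_jitter_mm: 0.2}
    - {name: novice, bias_voxels: 0, flip_rate: 0.22, slice_jitter_mm: 0.5}
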