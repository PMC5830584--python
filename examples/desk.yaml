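# Desk-scale pipeline configuration. Every analysis threshold is surfaced
# here with its default value; generator sizes are reduced for fast runs.
generator:
  n_layers: 6
  units_per_layer: [20, 22, 24, 26, 28, 30]
  n_voxels: 150
  tr: 2.0
  time_step: 1.0
  session_length: 120
  n_train_sessions: 3
  n_test_sessions: 1
  n_test_repeats: 3
  noise_sd: 1.0
  seed: 7
hierarchy:
  categories_per_subgroup: 2
  exemplars_per_category_mean: 15
thresholds:
  variance: 0.99      # PCA retained-variance threshold (both stages)
  q: 0.01             # FDR threshold for the predictable-voxel mask
  r: 0.2              # accuracy threshold for the predictable-voxel mask
  alpha: 0.01         # Bonferroni level for cluster-specific regions
  block_length: 20.0  # seconds per permutation block
permutations:
  accuracy: 500
  modularity: 1000
  semantic: 1000
k_range: [2, 8]
n_random_exemplars: 500
n_ceiling_sim: 500
n_restarts: 30
seed: 7
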