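# Default profile: elitist GA with history-adaptive mutation, then PCA + SVR.
# Remove the `synthetic` block and add
#   input: {matrix: path/to/matrix.csv, target: path/to/target.csv}
# to run on real descriptor data.
seed: 7
synthetic:
  n_samples: 30
  n_descriptors: 200
  n_informative: 5
  noise_sigma: 0.5
  n_constant: 5
  n_duplicates: 5
  rng_seed: 0
split:
  n_train: 24
select:
  method: ga
  variant: rec
  model: pls
  population: 50
  generations: 200
  pc: 0.5
  pm: 0.01
  cv_folds: 5
  history_window: 50
  n_keep: 20
model:
  family: svr
  pca_components: 5
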