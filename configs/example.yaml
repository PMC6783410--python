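# Example pipeline configuration (all fields optional; defaults shown
# where they differ from the library defaults). Run with:
#   gliorad run-all --config configs/example.yaml
workdir: scratch/example_run

cohort:
  n_cases: 30
  grid_shape: [48, 48, 48]
  spacing_mm: [2.0, 2.0, 2.0]
  seed: 0

texture:
  n_gray_bins: 32
  distance: 1
  min_voi_voxels: 8

spca_threshold: auto      # or a number, e.g. 1.69
spca_k: 10
spca_seed: 0

lasso_outer_k: 10
lasso_repeats: 5
lasso_seed: 0
lasso_n_lambda: 50

survivor_cutoffs: [10, 11, 12, 13, 14, 15, 16, 17]

# Real-data mode: supply both to bypass the image stages.
# features_csv: path/to/features.csv
# clinical_csv: path/to/clinical.csv
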