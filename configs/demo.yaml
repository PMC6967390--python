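# Bundled synthetic demo: small enough to run end to end in seconds.
p: 100
n: 160
module_sizes: [12, 10, 8]
within_module_partial_corr: 0.4
zero_inflation: 0.05
n_markers: 10
cas_module_index: 0
labeled_fraction: 0.5
annotated_fraction: 0.9
min_frac: 0.10
nlambda: 30
lambda_min_ratio: 0.1
screen: true
symmetrize_rule: or
n_rotations: 20
cluster_n_draws: 200
eta: 0.0001
cv_folds: 5
max_sweeps: 100
angle_grid_size: 180
n_perm: 1000
n_location_reps: 100
seed_simulate: 11
seed_labels: 12
seed_ric: 13
seed_cluster: 14
seed_cv: 15
seed_predict: 16
seed_colocate: 17
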