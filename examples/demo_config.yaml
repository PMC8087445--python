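# Demo pipeline configuration: a small synthetic study that runs end to end
# (simulate -> preprocess -> clock -> metrics -> covariates -> delta-age
# models -> enrichment) in a few minutes on one core.
seed: 1
out_dir: run
n_individuals: 60
n_sites: 1000
n_age_sites: 120
rank_acceleration: 0.1
longitudinal_fraction: 0.15
knn_k: 10
alpha: 0.1
n_folds: 5
run_enrichment: true
run_associations: true
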