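# full-workflow configuration for `toxprofiler run-all`
seed: 7
outdir: out/full

simulate:
  enabled: true
  n_compounds: 250
  n_assays: 16
  n_relevant_assays: 3
  association_odds: 8.0
  are_association_odds: 8.0
  missing_rate: 0.1
  curve_noise_sd: 5.0
  target_active_rate: 0.3
  target_toxic_rate: 0.35

curves:
  noise_threshold: 10.0

profile:
  ra_threshold: 0.25
  min_matching_actives: 10

qsar:
  enabled: true
  folds: 5
  rf_trees: 100
  knn_k: 5
  ad_k: 5
  ad_z: 0.5
  ratio: [750, 800]
  run_cv: true

toxicophore:
  enabled: true
  fragments:
    - id: frag_cf3
      pattern: C(F)(F)F
    - id: frag_methylamide
      pattern: N(C)C=O
  radius: 2
  min_support: 5
  rank: true
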