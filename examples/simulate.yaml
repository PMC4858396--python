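# synthetic-data generator configuration (SimulationConfig fields)
n_compounds: 300
n_assays: 20
n_relevant_assays: 3
association_odds: 8.0
are_association_odds: 8.0
assay_base_active_rate: 0.2
missing_rate: 0.1
curve_noise_sd: 5.0
target_active_rate: 0.15
target_toxic_rate: 0.5
seed: 7
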