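cutoff_date: '2021-12-31'
ensemble_size: 1
ffn_layers: 1
fine_tune_strategy: modality_specific
hidden_width: 16
log_level: INFO
max_epochs: 3
message_passing_depth: 2
min_stratum_size: 5
n_boot: 100
n_total: 500
noise_sd: 0.3
out_dir: runs/mini
patience: 3
refine_cutoff_date: '2022-12-31'
seed: 3
surrogate_n: 400
tasks_file: null
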