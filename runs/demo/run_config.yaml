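cutoff_date: '2021-12-31'
ensemble_size: 1
ffn_layers: 2
fine_tune_strategy: modality_specific
hidden_width: 64
log_level: INFO
max_epochs: 30
message_passing_depth: 2
min_stratum_size: 5
n_boot: 500
n_total: 2000
noise_sd: 0.3
out_dir: runs/demo
patience: 5
refine_cutoff_date: '2022-12-31'
seed: 7
surrogate_n: 2000
tasks_file: null
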