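# Shared run configuration for the numbered analysis drivers.
# A 2000-compound study keeps every step under ~2 minutes on one core;
# scale n_total up for tighter error estimates.
out_dir: results/run
seed: 1
n_total: 2000
noise_sd: 0.3
hidden_width: 64
message_passing_depth: 2
ffn_layers: 2
ensemble_size: 2
max_epochs: 40
patience: 6
fine_tune_strategy: modality_specific
n_boot: 1000
min_stratum_size: 5
surrogate_n: 4000
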