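{
  "config_hash": "186344cbb0508e98",
  "elapsed_seconds": 3.01,
  "inputs": {
    "model.npz": "75c40ea5071ed1dc"
  },
  "outputs": {
    "distillation.csv": "0883db0afec92f0f",
    "model_student.npz": "30a19979ed1d33a7",
    "surrogate.csv": "cd08929fe78f9a82"
  },
  "seed": 534926514,
  "stage": "surrogate"
}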