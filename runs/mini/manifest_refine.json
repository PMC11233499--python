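{
  "config_hash": "186344cbb0508e98",
  "elapsed_seconds": 2.633,
  "inputs": {
    "model.npz": "75c40ea5071ed1dc"
  },
  "outputs": {
    "model_fine_tuned.npz": "fbf8c44456c118e0",
    "model_retrained.npz": "62e8e6b9ae52936e",
    "refinement.csv": "35a4dac971af92bc"
  },
  "seed": 1598521061,
  "stage": "refine"
}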