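{
  "config_hash": "23de8a9a82b626b5",
  "elapsed_seconds": 1.087,
  "inputs": {
    "model.npz": "1d7e20b3bd1a4a36"
  },
  "outputs": {
    "evaluation.csv": "beab2324638d957b",
    "evaluation.json": "227b436a19abe492"
  },
  "seed": 1188230234,
  "stage": "evaluate"
}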