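{
  "config_hash": "433af69113e20637",
  "elapsed_seconds": 2.917,
  "inputs": {
    "model.npz": "a6c56bcdc329a74e"
  },
  "outputs": {
    "evaluation.csv": "beab2324638d957b",
    "evaluation.json": "227b436a19abe492"
  },
  "seed": 1188230234,
  "stage": "evaluate"
}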