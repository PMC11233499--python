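{
  "config_hash": "433af69113e20637",
  "elapsed_seconds": 25.173,
  "inputs": {
    "measurements.csv": "7ae75be570c83ad3"
  },
  "outputs": {
    "model.npz": "a6c56bcdc329a74e"
  },
  "seed": 1318712413,
  "stage": "train"
}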