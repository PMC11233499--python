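{
  "config_hash": "23de8a9a82b626b5",
  "elapsed_seconds": 11.967,
  "inputs": {
    "measurements.csv": "7ae75be570c83ad3"
  },
  "outputs": {
    "model.npz": "1d7e20b3bd1a4a36"
  },
  "seed": 1318712413,
  "stage": "train"
}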