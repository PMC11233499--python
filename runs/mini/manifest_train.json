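{
  "config_hash": "186344cbb0508e98",
  "elapsed_seconds": 0.948,
  "inputs": {
    "measurements.csv": "b79661419ba3dd86"
  },
  "outputs": {
    "model.npz": "75c40ea5071ed1dc"
  },
  "seed": 2105776027,
  "stage": "train"
}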