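{
  "config_hash": "186344cbb0508e98",
  "elapsed_seconds": 0.334,
  "inputs": {
    "model.npz": "75c40ea5071ed1dc"
  },
  "outputs": {
    "evaluation.csv": "a19a5977b876fae9",
    "evaluation.json": "b2f7f6d00066230e"
  },
  "seed": 598965220,
  "stage": "evaluate"
}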