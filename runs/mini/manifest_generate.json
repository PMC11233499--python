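{
  "config_hash": "186344cbb0508e98",
  "elapsed_seconds": 1.282,
  "inputs": {},
  "outputs": {
    "compounds.csv": "09769a45407cf860",
    "ground_truth.json": "0ae627abf076cba5",
    "measurements.csv": "b79661419ba3dd86"
  },
  "seed": 457190280,
  "stage": "generate"
}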