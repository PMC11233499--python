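{
  "config_hash": "186344cbb0508e98",
  "elapsed_seconds": 0.026,
  "inputs": {
    "compounds.csv": "09769a45407cf860",
    "measurements.csv": "b79661419ba3dd86"
  },
  "outputs": {
    "label_matrix.npz": "8555d27796fd4148"
  },
  "seed": 960329833,
  "stage": "ingest"
}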